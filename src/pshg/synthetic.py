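"""Physics-based synthetic widefield P-SHG data generator.

Forward-simulates measurement stacks of collagen-like fiber fields with
known per-pixel ground truth (susceptibility ratio R, in-plane orientation
delta, out-of-plane tilt alpha, chirality, amplitude), so every downstream
stage of the pipeline has a parameter-recovery oracle and group-labelled
datasets exist without original tissue data.

Model
-----
Each fiber pixel carries a cylindrically symmetric (C6, Kleinman-restricted)
second-order susceptibility with one antisymmetric chiral element.  With the
fiber axis ``zf`` at in-plane angle ``delta`` (counter-clockwise from the
image horizontal) and out-of-plane tilt ``alpha``, the incident Jones field
(no component along the propagation axis) is projected onto the fiber frame
and the second-order polarization is, with chi2_zxx = 1,

    Pz = (Ex^2 + Ey^2) + R * Ez^2
    Px = 2 Ex Ez + 2 C Ey Ez
    Py = 2 Ey Ez - 2 C Ex Ez

where R = chi2_zzz/chi2_zxx and C = chi2_xyz/chi2_zxx.  P is rotated back
to the lab frame, the longitudinal (propagation-axis) component is dropped,
and the transverse components form the outgoing Stokes vector of the
coherent, fully polarized emission.  Birefringence, scattering and
focal-volume averaging are omitted; a single fiber therefore emits DCP = 1
light, while incoherent summation of crossing fiber layers (``n_layers`` in
the preset) yields DCP < 1.

Conventions (fixed, shared with :mod:`pshg.polarimetry` tests):
RCP = (1, +i)/sqrt(2), LCP = (1, -i)/sqrt(2); outgoing
s3 = -2 Im(PX conj(PY)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .polarimetry import (
    MeasurementStack,
    PolState,
    STATE_ORDER,
    enumerate_measurement_scheme,
)

__all__ = [
    "FiberField",
    "GroupPreset",
    "NoiseModel",
    "default_presets",
    "generate_fiber_field",
    "forward_stokes",
    "analyze_intensity",
    "render_measurement",
    "render_stack",
    "simulate_core",
    "generate_dataset",
    "calibrate_r_branch",
    "icp_background_stats",
    "write_dataset",
    "SyntheticCore",
    "SyntheticDataset",
]

#: Incident Jones vectors (Ex, Ey) in the lab frame, unit norm.
JONES = {
    PolState.HLP: np.array([1.0, 0.0], dtype=complex),
    PolState.VLP: np.array([0.0, 1.0], dtype=complex),
    PolState.RCP: np.array([1.0, 1.0j], dtype=complex) / np.sqrt(2.0),
    PolState.LCP: np.array([1.0, -1.0j], dtype=complex) / np.sqrt(2.0),
}

#: Analyzer unit Stokes directions (s1, s2, s3) for I = (s0 + shat.s)/2.
ANALYZER_STOKES = {
    PolState.HLP: np.array([1.0, 0.0, 0.0]),
    PolState.VLP: np.array([-1.0, 0.0, 0.0]),
    PolState.RCP: np.array([0.0, 0.0, 1.0]),
    PolState.LCP: np.array([0.0, 0.0, -1.0]),
}


@dataclass
class FiberField:
    """Per-pixel synthetic ground truth for one fiber layer.

    ``delta`` and ``alpha`` are degrees; ``r_true`` is chi2_zzz/chi2_zxx
    (> 1 on fibers); ``c_true`` the chiral ratio chi2_xyz/chi2_zxx;
    ``amplitude`` scales the emitted intensity (arbitrary units).
    """

    fiber_mask: np.ndarray
    delta: np.ndarray
    alpha: np.ndarray
    r_true: np.ndarray
    c_true: np.ndarray
    amplitude: np.ndarray
    #: phase retardance (degrees) of the chiral element relative to the
    #: achiral ones.  A purely real tensor (phase 0) produces exactly zero
    #: SHG-CD — swapping RCP/LCP conjugates the incident field and a real
    #: tensor makes |P| conjugation-invariant — so the default quadrature
    #: phase is what lets chirality show up in the dichroism at all.
    chiral_phase_deg: float = 90.0

    def __post_init__(self) -> None:
        m = self.fiber_mask
        if m.any():
            if np.any(self.r_true[m] <= 1.0):
                raise ValueError("r_true must be > 1 on fiber pixels")
            if np.any(np.abs(self.alpha[m]) >= 90.0):
                raise ValueError("|alpha| must be < 90 degrees")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fiber_mask.shape

    @property
    def fiber_fraction(self) -> float:
        return float(self.fiber_mask.mean())


@dataclass
class NoiseModel:
    """Detector noise: Gaussian background (dark) plus optional shot noise.

    ``background_mean``/``background_sd`` are counts added everywhere;
    ``shot_noise`` replaces the clean signal by a Poisson draw with mean
    ``signal * shot_scale`` rescaled back (``shot_scale`` counts per
    photoelectron-equivalent; larger means weaker shot noise).
    """

    background_mean: float = 10.0
    background_sd: float = 2.0
    shot_noise: bool = True
    shot_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.shot_scale <= 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroupPreset:
    """Generation parameters for one tissue group.

    Defaults emulate the qualitative normal-vs-tumor contrasts of breast
    tissue P-SHG: tumor stroma shows lower SHG amplitude and pixel density,
    a higher susceptibility ratio R (and hence DCP), and straighter, less
    dispersed fibers (narrower dichroism spreads).  Values are loaded from
    the packaged ``data/presets.yaml`` by :func:`default_presets`.
    """

    label: str
    r_mean: float
    r_sd: float
    fiber_density_target: float
    orientation_dispersion: float  # SD of tangent-angle increments, deg/step
    alpha_sd: float  # SD of per-fiber out-of-plane tilt, deg
    amplitude_mean: float
    amplitude_sd: float = 0.0
    chirality: float = 0.0
    n_layers: int = 1  # incoherently summed crossing-fiber layers
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fiber_density_target < 1.0:
            raise ValueError("fiber_density_target must be in [0, 1)")
        if self.r_mean <= 1.0:
            raise ValueError("r_mean must be > 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)


def default_presets() -> dict[str, GroupPreset]:
    """Load the packaged normal/tumor presets (data/presets.yaml)."""
    text = resources.files("pshg").joinpath("data/presets.yaml").read_text()
    raw = yaml.safe_load(text)
    presets = {k: GroupPreset(label=k, **v) for k, v in raw.items()}
    if {"normal", "tumor"} <= presets.keys():
        n, t = presets["normal"], presets["tumor"]
        ok = (
            t.fiber_density_target < n.fiber_density_target
            and t.amplitude_mean < n.amplitude_mean
            and t.r_mean > n.r_mean
            and t.orientation_dispersion < n.orientation_dispersion
        )
        if not ok:
            raise ValueError("presets violate the normal/tumor contrast ordering")
    return presets


# ---------------------------------------------------------------------------
# fiber field generation
# ---------------------------------------------------------------------------


def _stamp_disk(
    arrs: dict[str, np.ndarray],
    mask: np.ndarray,
    r0: int,
    c0: int,
    radius: int,
    values: dict[str, float],
) -> None:
    n = mask.shape[0]
    lo_r, hi_r = max(r0 - radius, 0), min(r0 + radius + 1, n)
    lo_c, hi_c = max(c0 - radius, 0), min(c0 + radius + 1, mask.shape[1])
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr, cc = np.ogrid[lo_r:hi_r, lo_c:hi_c]
    disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    sub = (slice(lo_r, hi_r), slice(lo_c, hi_c))
    mask[sub][disk] = True
    for key, val in values.items():
        arrs[key][sub][disk] = val


def generate_fiber_field(
    size: int,
    preset: GroupPreset,
    seed: int | np.random.Generator,
    max_attempts_factor: int = 50,
) -> FiberField:
    """Draw random smooth curvilinear fibers until the density target is met.

    Fibers are random-walk polylines: the tangent angle performs a Gaussian
    walk with step SD ``preset.orientation_dispersion`` (degrees per pixel
    step), so large dispersion produces wavy fibers.  Each polyline is
    dilated to a 2-6 pixel width; per-pixel ``delta`` is the local tangent,
    while ``alpha``, ``r_true`` and ``amplitude`` are drawn once per fiber.
    Deterministic for a fixed seed.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mask = np.zeros((size, size), dtype=bool)
    arrs = {
        "delta": np.zeros((size, size)),
        "alpha": np.zeros((size, size)),
        "r_true": np.full((size, size), 2.0),
        "c_true": np.zeros((size, size)),
        "amplitude": np.zeros((size, size)),
    }
    target = preset.fiber_density_target
    if target > 0:
        # expected pixels per fiber ~ length * width
        est_per_fiber = 1.2 * size * 4
        max_fibers = max(int(max_attempts_factor * target * size * size / est_per_fiber), 10)
        n_fibers = 0
        while mask.mean() < target:
            if n_fibers >= max_fibers:
                raise RuntimeError(
                    f"fiber density target {target} unreachable after "
                    f"{max_fibers} fibers (reached {mask.mean():.3f})"
                )
            n_fibers += 1
            # per-fiber draws
            r_f = max(float(rng.normal(preset.r_mean, preset.r_sd)), 1.05)
            alpha_f = float(np.clip(rng.normal(0.0, preset.alpha_sd), -80.0, 80.0))
            amp_f = max(float(rng.normal(preset.amplitude_mean, preset.amplitude_sd)), 0.0)
            width = int(rng.integers(2, 7))
            radius = max(width // 2, 1)
            n_steps = int(rng.integers(size // 2, int(1.5 * size)))
            r0 = float(rng.uniform(0, size))
            c0 = float(rng.uniform(0, size))
            theta = float(rng.uniform(0.0, 180.0))
            steps = rng.normal(0.0, preset.orientation_dispersion, n_steps)
            for k in range(n_steps):
                theta = theta + steps[k]
                rad = np.deg2rad(theta)
                # image rows grow downward; delta is CCW from horizontal
                c0 += np.cos(rad)
                r0 -= np.sin(rad)
                ri, ci = int(round(r0)), int(round(c0))
                if not (-radius <= ri < size + radius and -radius <= ci < size + radius):
                    break
                _stamp_disk(
                    arrs,
                    mask,
                    ri,
                    ci,
                    radius,
                    {
                        "delta": theta % 180.0,
                        "alpha": alpha_f,
                        "r_true": r_f,
                        "c_true": preset.chirality,
                        "amplitude": amp_f,
                    },
                )
            if mask.mean() >= target:
                break
    field_arrs = {k: np.where(mask, v, 0.0) for k, v in arrs.items()}
    field_arrs["r_true"] = np.where(mask, arrs["r_true"], 2.0)  # keep >1 invariant off-fiber harmless
    return FiberField(fiber_mask=mask, **field_arrs)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def forward_stokes(
    field: FiberField, psg: PolState
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact outgoing Stokes maps (s0, s1, s2, s3) for one incident state.

    Implements the fiber-frame susceptibility contraction described in the
    module docstring, vectorized over fiber pixels; non-fiber pixels emit
    zero.  The emission is coherent and fully polarized:
    s0 = sqrt(s1^2 + s2^2 + s3^2) on every fiber pixel.
    """
    psg = PolState(psg)
    shape = field.shape
    s = [np.zeros(shape) for _ in range(4)]
    m = field.fiber_mask
    if not m.any():
        return tuple(s)  # type: ignore[return-value]

    delta = np.deg2rad(field.delta[m])
    alpha = np.deg2rad(field.alpha[m])
    r = field.r_true[m]
    c = field.c_true[m]
    amp = field.amplitude[m]

    cd, sd = np.cos(delta), np.sin(delta)
    ca, sa = np.cos(alpha), np.sin(alpha)
    # fiber frame in lab coordinates (X, Y transverse; Z propagation)
    zf = np.stack([ca * cd, ca * sd, sa])  # fiber axis
    xf = np.stack([-sd, cd, np.zeros_like(sd)])  # in-image transverse
    yf = np.stack(
        [-sa * cd, -sa * sd, ca]
    )  # zf x xf, completes right-handed frame

    e_lab = JONES[psg]  # (Ex, Ey), no longitudinal component
    ez = e_lab[0] * zf[0] + e_lab[1] * zf[1]
    ex = e_lab[0] * xf[0] + e_lab[1] * xf[1]
    ey = e_lab[0] * yf[0] + e_lab[1] * yf[1]

    c_eff = c * np.exp(1j * np.deg2rad(field.chiral_phase_deg))
    pz = (ex * ex + ey * ey) + r * ez * ez
    px = 2.0 * ex * ez + 2.0 * c_eff * ey * ez
    py = 2.0 * ey * ez - 2.0 * c_eff * ex * ez

    # back to lab, keep transverse components only
    p_lab_x = px * xf[0] + py * yf[0] + pz * zf[0]
    p_lab_y = px * xf[1] + py * yf[1] + pz * zf[1]

    s0 = amp * (np.abs(p_lab_x) ** 2 + np.abs(p_lab_y) ** 2)
    s1 = amp * (np.abs(p_lab_x) ** 2 - np.abs(p_lab_y) ** 2)
    s2 = amp * 2.0 * np.real(p_lab_x * np.conj(p_lab_y))
    s3 = amp * -2.0 * np.imag(p_lab_x * np.conj(p_lab_y))
    for arr, vals in zip(s, (s0, s1, s2, s3)):
        arr[m] = vals
    return tuple(s)  # type: ignore[return-value]


def analyze_intensity(
    stokes: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    psa: PolState,
) -> np.ndarray:
    """Project an outgoing Stokes field onto the analyzer: I = (s0 + shat.s)/2."""
    s0, s1, s2, s3 = stokes
    shat = ANALYZER_STOKES[PolState(psa)]
    return 0.5 * (s0 + shat[0] * s1 + shat[1] * s2 + shat[2] * s3)


def _apply_noise(
    clean: np.ndarray, noise: NoiseModel | None, rng: np.random.Generator
) -> np.ndarray:
    # the analyzer projection can undershoot zero by float rounding
    clean = np.maximum(clean, 0.0)
    if noise is None:
        return clean
    out = clean
    if noise.shot_noise:
        out = rng.poisson(np.maximum(out, 0.0) * noise.shot_scale) / noise.shot_scale
    out = out + rng.normal(noise.background_mean, noise.background_sd, clean.shape)
    return np.maximum(out, 0.0)


def render_measurement(
    field: FiberField,
    psg: PolState,
    psa: PolState,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render one analyzed intensity image (optionally noisy)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = analyze_intensity(forward_stokes(field, psg), psa)
    return _apply_noise(clean, noise, rng)


def _sum_layer_stokes(fields: list[FiberField], psg: PolState):
    """Incoherent (Stokes-additive) sum over crossing fiber layers."""
    acc = None
    for f in fields:
        s = forward_stokes(f, psg)
        acc = s if acc is None else tuple(a + b for a, b in zip(acc, s))
    return acc


def render_stack(
    fields: FiberField | list[FiberField],
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> MeasurementStack:
    """Render the full 16-state measurement stack for a fiber field.

    Multiple fields are summed incoherently (crossing-fiber layers), which
    is the mechanism producing DCP < 1 in the synthetic data.
    """
    if isinstance(fields, FiberField):
        fields = [fields]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_psg = {p: _sum_layer_stokes(fields, p) for p in STATE_ORDER}
    images = {}
    for psg, psa in enumerate_measurement_scheme():
        clean = analyze_intensity(per_psg[psg], psa)
        images[(psg, psa)] = _apply_noise(clean, noise, rng)
    return MeasurementStack(images=images)


@dataclass
class SyntheticCore:
    """One simulated tissue core: stack, ground truth layers and label."""

    core_id: str
    label: str
    stack: MeasurementStack
    fields: list[FiberField]

    @property
    def field(self) -> FiberField:
        return self.fields[0]

    def truth_summary(self) -> dict:
        masks = [f.fiber_mask for f in self.fields]
        any_mask = np.logical_or.reduce(masks)
        vals = {
            "core_id": self.core_id,
            "label": self.label,
            "fiber_fraction": float(any_mask.mean()),
            "n_layers": len(self.fields),
        }
        r_all = np.concatenate([f.r_true[f.fiber_mask] for f in self.fields]) if any_mask.any() else np.array([])
        vals["r_true_mean"] = float(r_all.mean()) if r_all.size else float("nan")
        vals["amplitude_mean"] = float(
            np.concatenate([f.amplitude[f.fiber_mask] for f in self.fields]).mean()
        ) if any_mask.any() else float("nan")
        return vals


@dataclass
class SyntheticDataset:
    cores: list[SyntheticCore]
    manifest: dict

    def labels(self) -> dict[str, str]:
        return {c.core_id: c.label for c in self.cores}


def simulate_core(
    preset: GroupPreset,
    size: int,
    seed: int | np.random.Generator,
    noise: NoiseModel | None = "preset",  # type: ignore[assignment]
) -> tuple[MeasurementStack, list[FiberField]]:
    """Simulate one core: fiber layers from the preset plus rendered stack."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_layer_target = preset.fiber_density_target / preset.n_layers
    layer_preset = GroupPreset(**{**asdict(preset), "fiber_density_target": per_layer_target,
                                  "noise": asdict(preset.noise)})
    fields = [
        generate_fiber_field(size, layer_preset, rng) for _ in range(preset.n_layers)
    ]
    if noise == "preset":
        noise = preset.noise
    stack = render_stack(fields, noise=noise, seed=rng)
    return stack, fields


def generate_dataset(
    n_cores_per_group: int,
    presets: dict[str, GroupPreset] | None = None,
    core_size: int = 512,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a labelled multi-core dataset (the synthetic microarray).

    Each core gets a child seed spawned deterministically from the master
    seed, so the dataset is reproducible core-by-core.
    """
    if n_cores_per_group < 1:
        raise ValueError("n_cores_per_group must be >= 1")
    if presets is None:
        presets = default_presets()
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(presets) * n_cores_per_group)
    cores: list[SyntheticCore] = []
    i = 0
    for label in sorted(presets):
        preset = presets[label]
        for k in range(n_cores_per_group):
            rng = np.random.default_rng(children[i])
            i += 1
            stack, fields = simulate_core(preset, core_size, rng)
            cores.append(
                SyntheticCore(
                    core_id=f"{label}_{k:02d}", label=label, stack=stack, fields=fields
                )
            )
    manifest = {
        "seed": seed,
        "core_size": core_size,
        "n_cores_per_group": n_cores_per_group,
        "groups": {
            label: {
                **{k: v for k, v in asdict(presets[label]).items() if k != "noise"},
                "noise": asdict(presets[label].noise),
            }
            for label in sorted(presets)
        },
        "cores": [{"core_id": c.core_id, "label": c.label} for c in cores],
    }
    return SyntheticDataset(cores=cores, manifest=manifest)


def icp_background_stats(noise: NoiseModel) -> tuple[float, float]:
    """Background mean/SD of the reconstructed ICP map under a noise model.

    Each analyzed background image is N(mu, sigma); the reconstructed
    s0 of one PSG state is the sum of its four images over 2, i.e.
    N(2 mu, sigma), and ICP averages the two independent circular-state
    s0 maps, giving N(2 mu, sigma/sqrt(2)).  Used to drive the SNR mask
    on synthetic data without measuring a background region.
    """
    return 2.0 * noise.background_mean, noise.background_sd / np.sqrt(2.0)


# ---------------------------------------------------------------------------
# branch calibration for the R-ratio quadratic
# ---------------------------------------------------------------------------


def calibrate_r_branch(r_probe: float = 2.0, tol: float = 1e-6) -> str:
    """Select the R-ratio root that round-trips the forward model.

    Simulates a single in-plane achiral probe fiber with known ratio
    ``r_probe`` noise-free, reconstructs the reduced Stokes maps, and
    brute-force checks which quadratic root reproduces the ground truth.
    Returns ``"plus"`` or ``"minus"``.  At ``r_probe = 3`` the roots
    coincide and ``"minus"`` is returned.
    """
    from .polarimetry import compute_r_ratio, reconstruct_stokes

    if r_probe <= 1.0:
        raise ValueError("r_probe must be > 1")
    n = 4
    shape = (n, n)
    probe = FiberField(
        fiber_mask=np.ones(shape, dtype=bool),
        delta=np.full(shape, 30.0),
        alpha=np.zeros(shape),
        r_true=np.full(shape, float(r_probe)),
        c_true=np.zeros(shape),
        amplitude=np.ones(shape),
    )
    stack = render_stack(probe, noise=None, seed=0)
    st = reconstruct_stokes(stack)
    errs = {}
    for br in ("minus", "plus"):
        r_map, valid = compute_r_ratio(st, branch=br)
        errs[br] = (
            float(np.nanmax(np.abs(r_map[valid] - r_probe))) if valid.any() else np.inf
        )
    if errs["minus"] <= tol and errs["plus"] <= tol:
        return "minus"
    best = min(errs, key=errs.get)
    if errs[best] > tol * max(r_probe, 1.0):
        raise RuntimeError(
            f"branch calibration failed at r_probe={r_probe}: errors {errs}"
        )
    return best


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a dataset to disk in the layout the pipeline reads.

    Per core: a 16-page TIFF stack (page order = measurement scheme) and
    float TIFF ground-truth maps (delta, alpha, r) for the first layer;
    ``manifest.json`` maps cores to labels; ``truth_summary.csv`` holds
    per-core ground-truth aggregates.
    """
    import pandas as pd
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for core in ds.cores:
        pages = np.stack(
            [core.stack[(g, a)] for g, a in enumerate_measurement_scheme()]
        ).astype(np.float32)
        tifffile.imwrite(out / f"{core.core_id}_stack.tif", pages)
        f = core.field
        for name, arr in (("delta", f.delta), ("alpha", f.alpha), ("r", f.r_true)):
            truth = np.where(f.fiber_mask, arr, np.nan).astype(np.float32)
            tifffile.imwrite(out / f"{core.core_id}_truth_{name}.tif", truth)
        rows.append(core.truth_summary())
    pd.DataFrame(rows).to_csv(out / "truth_summary.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(ds.manifest, indent=2, sort_keys=True))
    return out
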