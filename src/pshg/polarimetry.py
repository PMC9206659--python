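"""Reduced Stokes-vector reconstruction and polarimetric parameter maps.

Widefield P-SHG microscopy probes a sample with four incident polarization
states (polarization state generator, PSG) and analyzes the second-harmonic
signal in the same four states (polarization state analyzer, PSA), giving a
16-image measurement stack.  The four states are left circular (LCP),
horizontal linear (HLP), right circular (RCP) and vertical linear (VLP),
realized by liquid-crystal variable retardances of 1/4, 1/2, 3/4 and 1 wave.

Because only four analyzer states are measured, the reconstruction is a
*reduced* Stokes polarimetry: per PSG state we recover s0, s1 and s3 of the
outgoing SHG Stokes vector (s2 is not measured).  From the reconstructed
Stokes maps five per-pixel polarimetric parameters are computed:

* ``ICP``     — orientation-independent SHG intensity, mean of the circular
  incident-state total intensities.
* ``R``       — achiral susceptibility ratio chi2_zzz/chi2_zxx with z along
  the fiber axis, obtained from the circular-state s0 and s3 elements.
* ``DCP``     — degree of circular polarization of the SHG signal.
* ``SHG-CD``  — normalized circular dichroism, in [-2, 2].
* ``SHG-LD``  — normalized linear dichroism, in [-2, 2].

Sign conventions (documented, configurable): s1 = I(HLP) - I(VLP),
s3 = I(RCP) - I(LCP).  Background pixels and pixels where a parameter is
undefined are marked with NaN and excluded by the validity mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "PolState",
    "STATE_ORDER",
    "RETARDANCE_WAVES",
    "MeasurementStack",
    "StokesMaps",
    "ParameterMaps",
    "enumerate_measurement_scheme",
    "reconstruct_stokes",
    "compute_icp",
    "compute_r_ratio",
    "compute_dcp",
    "compute_shg_cd",
    "compute_shg_ld",
    "snr_mask",
    "compute_parameter_maps",
]


class PolState(str, Enum):
    """One of the four generator/analyzer polarization states."""

    LCP = "lcp"
    HLP = "hlp"
    RCP = "rcp"
    VLP = "vlp"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed state order used everywhere (matches the retardance ramp).
STATE_ORDER: tuple[PolState, ...] = (
    PolState.LCP,
    PolState.HLP,
    PolState.RCP,
    PolState.VLP,
)

#: Retardance of the liquid-crystal variable retarder, in waves.
RETARDANCE_WAVES: dict[PolState, float] = {
    PolState.LCP: 0.25,
    PolState.HLP: 0.5,
    PolState.RCP: 0.75,
    PolState.VLP: 1.0,
}


def enumerate_measurement_scheme() -> list[tuple[PolState, PolState]]:
    """Return the 16 (PSG, PSA) state pairs in canonical order.

    PSG-major ordering with states LCP, HLP, RCP, VLP on both sides;
    this is also the page order of multi-page TIFF stacks.
    """
    return [(g, a) for g in STATE_ORDER for a in STATE_ORDER]


class StackKeyError(KeyError):
    """A (PSG, PSA) combination is missing from or duplicated in a stack."""


@dataclass
class MeasurementStack:
    """16 co-registered intensity images indexed by (PSG, PSA) state pair.

    Parameters
    ----------
    images
        Mapping ``(psg, psa) -> 2D float array`` of non-negative intensities
        (detector counts).  Exactly the 16 pairs of
        :func:`enumerate_measurement_scheme` must be present and all images
        must share one shape.
    pixel_size
        Optional lateral pixel size in micrometres (metadata only).
    """

    images: Mapping[tuple[PolState, PolState], np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        expected = set(enumerate_measurement_scheme())
        keys = {(PolState(g), PolState(a)) for g, a in self.images.keys()}
        missing = expected - keys
        extra = keys - expected
        if missing or extra:
            raise StackKeyError(
                f"measurement stack must hold exactly the 16 PSGxPSA pairs; "
                f"missing={sorted((g.value, a.value) for g, a in missing)} "
                f"extra={sorted((g.value, a.value) for g, a in extra)}"
            )
        self.images = {
            (PolState(g), PolState(a)): np.asarray(im, dtype=float)
            for (g, a), im in self.images.items()
        }
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"images have mismatched shapes: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("images must be 2D")
        for (g, a), im in self.images.items():
            if np.any(im < 0):
                raise ValueError(f"negative intensities in image ({g.value},{a.value})")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    def __getitem__(self, key: tuple[PolState, PolState]) -> np.ndarray:
        return self.images[(PolState(key[0]), PolState(key[1]))]


@dataclass
class StokesMaps:
    """Per-pixel reduced Stokes elements (s0, s1, s3) for each PSG state.

    ``residual`` holds, per PSG state, the per-pixel absolute difference
    between the two redundant total-intensity estimates
    ``I_HLP + I_VLP`` and ``I_RCP + I_LCP`` — a quality-control metric
    (zero on noise-free data).
    """

    s0: dict[PolState, np.ndarray]
    s1: dict[PolState, np.ndarray]
    s3: dict[PolState, np.ndarray]
    residual: dict[PolState, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.s0.values())).shape

    def physicality_violations(self, rtol: float = 1e-9) -> dict[PolState, int]:
        """Count pixels with |s1| > s0 or |s3| > s0 beyond tolerance.

        Violations are flagged, never clamped: they indicate noise or
        model breakdown and are useful QC output.
        """
        out = {}
        for p in self.s0:
            tol = rtol * np.maximum(np.abs(self.s0[p]), 1.0)
            bad = (np.abs(self.s1[p]) > self.s0[p] + tol) | (
                np.abs(self.s3[p]) > self.s0[p] + tol
            )
            out[p] = int(np.count_nonzero(bad))
        return out


def reconstruct_stokes(
    stack: MeasurementStack,
    sign_s1: int = 1,
    sign_s3: int = 1,
    dark_offset: float = 0.0,
) -> StokesMaps:
    """Reconstruct reduced Stokes maps from a 16-state measurement stack.

    For each PSG state ``p`` the four analyzed intensities give

    * ``s0 = (I[p,HLP] + I[p,VLP] + I[p,RCP] + I[p,LCP]) / 2`` — the average
      of the two redundant estimates ``I_H + I_V`` and ``I_R + I_L``,
    * ``s1 = I[p,HLP] - I[p,VLP]``,
    * ``s3 = I[p,RCP] - I[p,LCP]``,

    following a four-state Stokes analyzer algebra.  ``sign_s1`` and
    ``sign_s3`` allow flipping the sign conventions if the instrument's
    handedness differs.

    ``dark_offset`` is the mean detector background in counts, subtracted
    from every image before combination.  Without it the additive
    background inflates s0 (the differences s1, s3 are unaffected) and
    biases every intensity-normalized parameter — most visibly the
    R-ratio, whose estimate is dragged toward 1.

    Returns
    -------
    StokesMaps
        With the per-PSG consistency residual
        ``|(I_H + I_V) - (I_R + I_L)|`` attached.
    """
    if sign_s1 not in (-1, 1) or sign_s3 not in (-1, 1):
        raise ValueError("sign_s1 and sign_s3 must be +1 or -1")
    s0: dict[PolState, np.ndarray] = {}
    s1: dict[PolState, np.ndarray] = {}
    s3: dict[PolState, np.ndarray] = {}
    resid: dict[PolState, np.ndarray] = {}
    for p in STATE_ORDER:
        ih = stack[(p, PolState.HLP)] - dark_offset
        iv = stack[(p, PolState.VLP)] - dark_offset
        ir = stack[(p, PolState.RCP)] - dark_offset
        il = stack[(p, PolState.LCP)] - dark_offset
        lin = ih + iv
        circ = ir + il
        s0[p] = (lin + circ) / 2.0
        s1[p] = sign_s1 * (ih - iv)
        s3[p] = sign_s3 * (ir - il)
        resid[p] = np.abs(lin - circ)
    return StokesMaps(s0=s0, s1=s1, s3=s3, residual=resid)


def compute_icp(st: StokesMaps) -> np.ndarray:
    """Orientation-independent SHG intensity: (s0[RCP] + s0[LCP]) / 2."""
    return (st.s0[PolState.RCP] + st.s0[PolState.LCP]) / 2.0


def _r_from_a(a: np.ndarray, branch: str) -> np.ndarray:
    disc = a * a - 1.0
    root = np.sqrt(np.where(disc >= 0, disc, np.nan))
    if branch == "plus":
        return 1.0 + 2.0 * a + 2.0 * root
    return 1.0 + 2.0 * a - 2.0 * root


def compute_r_ratio(
    st: StokesMaps,
    branch: str = "auto",
    r_probe: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Susceptibility ratio R = chi2_zzz/chi2_zxx from circular-state Stokes.

    With ``A = (s0[RCP] + s0[LCP]) / (s3[RCP] - s3[LCP])`` the ratio solves
    a quadratic with roots ``R = 1 + 2A +/- 2*sqrt(A^2 - 1)``.  The two
    roots (``R`` and ``1 + 4/(R-1)``) produce identical circular-state data,
    so the branch cannot be decided per pixel from these maps alone:

    * ``branch="plus"`` / ``"minus"`` select a root explicitly (the plus
      root is >= 3, the minus root is <= 3 for A >= 1);
    * ``branch="auto"`` calibrates once against the forward fiber model: a
      probe fiber with known ratio ``r_probe`` (default 2.0, a typical
      collagen value) is simulated noise-free and the root that round-trips
      is used for the whole map.

    Pixels with ``|A| < 1`` (complex root — depolarization or noise outside
    the single-fiber model) or a zero denominator are marked invalid, not
    clamped.

    Returns
    -------
    (r_map, valid)
        ``r_map`` is NaN outside ``valid``.
    """
    if branch == "auto":
        from .synthetic import calibrate_r_branch  # deferred: avoids cycle

        branch = calibrate_r_branch(r_probe)
    if branch not in ("plus", "minus"):
        raise ValueError(f"unknown branch {branch!r}")
    num = st.s0[PolState.RCP] + st.s0[PolState.LCP]
    den = st.s3[PolState.RCP] - st.s3[PolState.LCP]
    with np.errstate(divide="ignore", invalid="ignore"):
        a = num / den
        valid = (den != 0) & np.isfinite(a) & (np.abs(a) >= 1.0)
        r = _r_from_a(np.where(valid, a, np.nan), branch)
    r = np.where(valid, r, np.nan)
    if valid.size and not valid.any():
        warnings.warn("R-ratio: no valid pixels (all |A| < 1 or zero denominator)")
    return r, valid


def compute_dcp(st: StokesMaps) -> np.ndarray:
    """Degree of circular polarization.

    DCP = (|s3[RCP]|/s0[RCP] + |s3[LCP]|/s0[LCP]) / 2; pixels with a
    non-positive s0 are NaN.  Values are not clamped here (clamping of
    noise-induced DCP > 1 happens in :func:`compute_parameter_maps`).
    """
    s0r = st.s0[PolState.RCP]
    s0l = st.s0[PolState.LCP]
    with np.errstate(divide="ignore", invalid="ignore"):
        dcp = 0.5 * (
            np.abs(st.s3[PolState.RCP]) / s0r + np.abs(st.s3[PolState.LCP]) / s0l
        )
    return np.where((s0r > 0) & (s0l > 0), dcp, np.nan)


def compute_shg_cd(st: StokesMaps) -> np.ndarray:
    """SHG circular dichroism: 2 (s0[RCP] - s0[LCP]) / (s0[RCP] + s0[LCP]).

    Bounded by [-2, 2]; pixels with zero total circular intensity are NaN.
    """
    s0r = st.s0[PolState.RCP]
    s0l = st.s0[PolState.LCP]
    tot = s0r + s0l
    with np.errstate(divide="ignore", invalid="ignore"):
        cd = 2.0 * (s0r - s0l) / tot
    return np.where(tot > 0, cd, np.nan)


def compute_shg_ld(st: StokesMaps) -> np.ndarray:
    """SHG linear dichroism: 2 (s0[VLP] - s0[HLP]) / (s0[VLP] + s0[HLP])."""
    s0v = st.s0[PolState.VLP]
    s0h = st.s0[PolState.HLP]
    tot = s0v + s0h
    with np.errstate(divide="ignore", invalid="ignore"):
        ld = 2.0 * (s0v - s0h) / tot
    return np.where(tot > 0, ld, np.nan)


def snr_mask(
    intensity: np.ndarray,
    background: tuple[float, float] | tuple[slice, slice],
    threshold: float = 3.0,
) -> np.ndarray:
    """Background-referenced signal mask.

    SNR is the z-score against background statistics:
    ``(pixel - mu_bg) / sigma_bg >= threshold``.  ``background`` is either
    an explicit ``(mean, sd)`` pair or a pair of slices designating a
    background rectangle of ``intensity`` from which the statistics are
    estimated.  The default threshold of 3 is the analysis cut; a threshold
    of 1 is conventional for display only.
    """
    intensity = np.asarray(intensity, dtype=float)
    if len(background) != 2:
        raise ValueError("background must be (mean, sd) or (row_slice, col_slice)")
    if isinstance(background[0], slice):
        region = intensity[background[0], background[1]]
        if region.size == 0:
            raise ValueError("empty background region")
        mu, sd = float(np.mean(region)), float(np.std(region))
    else:
        mu, sd = float(background[0]), float(background[1])
    if sd <= 0:
        raise ValueError("background standard deviation must be positive")
    return (intensity - mu) / sd >= threshold


@dataclass
class ParameterMaps:
    """The five polarimetric parameter maps plus a shared validity mask.

    All maps carry NaN outside ``valid``.  ``qc`` records pixel-bookkeeping
    counters (invalid R-ratio pixels, DCP values clamped to 1, Stokes
    physicality violations, consistency-residual statistics) and the
    R-ratio branch actually used.
    """

    icp: np.ndarray
    r_ratio: np.ndarray
    dcp: np.ndarray
    shg_cd: np.ndarray
    shg_ld: np.ndarray
    valid: np.ndarray
    qc: dict = field(default_factory=dict)

    #: canonical parameter order used by the texture/feature stage
    PARAM_NAMES = ("icp", "r_ratio", "dcp", "shg_cd", "shg_ld")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.PARAM_NAMES}


def compute_parameter_maps(
    st: StokesMaps,
    signal_mask: np.ndarray | None = None,
    branch: str = "auto",
    r_probe: float = 2.0,
) -> ParameterMaps:
    """Assemble the five parameter maps with a common validity mask.

    A pixel is valid when it passes the (optional) SNR ``signal_mask``, has
    positive circular and linear total intensities, and yields a real
    R-ratio root.  DCP values exceeding 1 (possible under noise, since DCP
    is a polarized-fraction ratio) are clamped to 1 and counted in
    ``qc["dcp_clamped"]``.
    """
    if branch == "auto":
        from .synthetic import calibrate_r_branch

        branch = calibrate_r_branch(r_probe)
    icp = compute_icp(st)
    r, r_valid = compute_r_ratio(st, branch=branch, r_probe=r_probe)
    dcp = compute_dcp(st)
    cd = compute_shg_cd(st)
    ld = compute_shg_ld(st)

    valid = r_valid & np.isfinite(dcp) & np.isfinite(cd) & np.isfinite(ld)
    if signal_mask is not None:
        valid = valid & np.asarray(signal_mask, dtype=bool)

    clamped = int(np.count_nonzero((dcp > 1.0) & valid))
    dcp = np.minimum(dcp, 1.0)

    out = {}
    for name, m in (
        ("icp", icp),
        ("r_ratio", r),
        ("dcp", dcp),
        ("shg_cd", cd),
        ("shg_ld", ld),
    ):
        out[name] = np.where(valid, m, np.nan)

    resid = np.stack([st.residual[p] for p in STATE_ORDER]) if st.residual else None
    qc = {
        "r_branch": branch,
        "n_pixels": int(valid.size),
        "n_valid": int(np.count_nonzero(valid)),
        "r_invalid": int(np.count_nonzero(~r_valid)),
        "dcp_clamped": clamped,
        "physicality_violations": {
            p.value: n for p, n in st.physicality_violations().items()
        },
        "consistency_residual_max": float(resid.max()) if resid is not None else None,
        "consistency_residual_mean": float(resid.mean()) if resid is not None else None,
    }
    return ParameterMaps(valid=valid, qc=qc, **out)
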