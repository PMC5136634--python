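"""The 20 objective GAW parameters.

Three families:

(A) glottal dynamics — time quotients (OQ, CQ, RQ, SQ, ASQ, SI) from the
    per-cycle phase durations, and amplitude dynamics (MADR, AMQ, GGI, PA);
(B) perturbation — amplitude (AP, AVI, mSH, SH) and period (mJT, JT)
    cycle-to-cycle measures;
(C) noise — spectral measures (HI, HNR, NNE, SPF) on the windowed GAW
    power spectrum.

All per-cycle quantities are computed cycle by cycle and then averaged over
the analyzed cycles; cycles where a quantity is undefined (e.g. zero closing
duration for SQ) are excluded with a warning.  A parameter that cannot be
computed at all is reported as an explicit undefined sentinel (NaN plus a
reason code), never silently as zero.

Amplitude dB scaling is 20*log10 on areas (the GAW is treated as the
waveform amplitude).  The SH normalization reference is 1 pixel, so the
denominator "mean dB-scaled dynamic range" is absolute and the SH value
depends on the pixel scale of the recording; this is deliberate and
documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .cycles import CycleSet, detect_cycles, DEFAULT_MAX_CYCLES
from .synth import GAWRecord

__all__ = [
    "PARAMETER_NAMES",
    "AnalysisConfig",
    "ParameterSet",
    "compute_time_quotients",
    "compute_amplitude_dynamics",
    "compute_amplitude_perturbation",
    "compute_time_perturbation",
    "spectral_measures",
    "compute_spectral_noise",
    "compute_all",
    "analyze_gaw",
]

#: Canonical order of the 20 parameter abbreviations.
PARAMETER_NAMES = [
    "AMQ", "ASQ", "CQ", "GGI", "MADR", "OQ", "PA", "RQ", "SI", "SQ",
    "AP", "AVI", "mSH", "SH", "JT", "mJT", "HI", "HNR", "NNE", "SPF",
]

_DB_CAP = 120.0  # cap for dB ratios with a vanishing numerator/denominator


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by cycle detection and parameter computation."""

    closure_threshold_rel: float = 0.0
    max_cycles: int = DEFAULT_MAX_CYCLES
    harmonic_bw_rel: float = 0.12  # half-width of each harmonic band, in F0 units
    pad_factor: int = 4            # FFT zero-padding, multiple of window length


@dataclass
class ParameterSet:
    """The 20 named parameter values for one GAW at one frame rate.

    Undefined values are NaN with the reason recorded in ``reasons``.
    """

    AMQ: float = np.nan
    ASQ: float = np.nan
    CQ: float = np.nan
    GGI: float = np.nan
    MADR: float = np.nan
    OQ: float = np.nan
    PA: float = np.nan
    RQ: float = np.nan
    SI: float = np.nan
    SQ: float = np.nan
    AP: float = np.nan
    AVI: float = np.nan
    mSH: float = np.nan
    SH: float = np.nan
    JT: float = np.nan
    mJT: float = np.nan
    HI: float = np.nan
    HNR: float = np.nan
    NNE: float = np.nan
    SPF: float = np.nan
    fps: float = np.nan
    n_cycles_used: int = 0
    reasons: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)

    def is_defined(self, name: str) -> bool:
        return np.isfinite(getattr(self, name))

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self) if f.name != "reasons"}

    def to_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in PARAMETER_NAMES})


def _mean_or_nan(values: list[float], out: dict, name: str, reason: str) -> float:
    if not values:
        out[name] = reason
        return np.nan
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# (A) time quotients
# ---------------------------------------------------------------------------

def compute_time_quotients(cycles: CycleSet) -> dict:
    """OQ, CQ, RQ, SQ, ASQ, SI: per-cycle phase-duration ratios, averaged.

    OQ = open/T, CQ = closing/T, RQ = (closed + opening)/closing,
    SQ = opening/closing, ASQ = SQ/(SQ+1), SI = (SQ-1)/(SQ+1).  Cycles with
    zero closing duration are excluded from RQ/SQ/ASQ/SI.
    """
    reasons: dict = {}
    oq, cq, rq, sq, asq, si = [], [], [], [], [], []
    n_skipped = 0
    for c in cycles.used:
        oq.append(c.open_s / c.T)
        cq.append(c.closing_s / c.T)
        if c.closing_s > 0:
            s = c.opening_s / c.closing_s
            sq.append(s)
            rq.append((c.closed_s + c.opening_s) / c.closing_s)
            asq.append(s / (s + 1.0))
            si.append((s - 1.0) / (s + 1.0))
        else:
            n_skipped += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} cycles with zero closing duration excluded from RQ/SQ/ASQ/SI",
            stacklevel=2,
        )
    return {
        "OQ": _mean_or_nan(oq, reasons, "OQ", "no cycles"),
        "CQ": _mean_or_nan(cq, reasons, "CQ", "no cycles"),
        "RQ": _mean_or_nan(rq, reasons, "RQ", "zero closing duration in all cycles"),
        "SQ": _mean_or_nan(sq, reasons, "SQ", "zero closing duration in all cycles"),
        "ASQ": _mean_or_nan(asq, reasons, "ASQ", "zero closing duration in all cycles"),
        "SI": _mean_or_nan(si, reasons, "SI", "zero closing duration in all cycles"),
        "reasons": reasons,
    }


# ---------------------------------------------------------------------------
# (A) amplitude dynamics
# ---------------------------------------------------------------------------

def compute_amplitude_dynamics(gaw: GAWRecord, cycles: CycleSet) -> dict:
    """MADR, AMQ, GGI, PA.

    Per cycle: MADR is the most negative first difference of the total area
    (pixels/frame, the maximum closing velocity); AMQ = dynamic range / MADR
    (frames, negative); GGI = min area / peak area; PA = (t_M(left) -
    t_M(right)) / T.  Cycle values are averaged; flat cycles (MADR = 0) are
    excluded from AMQ.
    """
    reasons: dict = {}
    a = gaw.total_area
    madr, amq, ggi, pa = [], [], [], []
    for c in cycles.used:
        d = np.diff(a[c.i_start : c.i_end])
        m = float(d.min()) if d.size else 0.0
        if m < 0:
            madr.append(m)
            amq.append(c.dyn_range / m)
        if c.peak_area > 0:
            ggi.append(c.min_area / c.peak_area)
        else:
            ggi.append(1.0)  # min == max == 0
        if c.t_M_left is not None:
            pa.append((c.t_M_left - c.t_M_right) / c.T)
    out = {
        "MADR": _mean_or_nan(madr, reasons, "MADR", "no negative area derivative"),
        "AMQ": _mean_or_nan(amq, reasons, "AMQ", "flat cycles (MADR = 0)"),
        "GGI": _mean_or_nan(ggi, reasons, "GGI", "no cycles"),
        "PA": _mean_or_nan(pa, reasons, "PA", "left/right halves missing"),
        "reasons": reasons,
    }
    return out


# ---------------------------------------------------------------------------
# (B) perturbation
# ---------------------------------------------------------------------------

def compute_amplitude_perturbation(cycles: CycleSet) -> dict:
    """AP, AVI, mSH, SH from the per-cycle dynamic ranges r_i.

    AP = mean over consecutive pairs of min(r_i, r_{i+1}) / max(r_i, r_{i+1});
    mSH = mean |20 log10(r_{i+1}/r_i)| (dB); AVI = 20 log10(SD(r)/mean(r))
    (dB-scaled coefficient of variation); SH(%) = 100 * mSH / mean_i
    (20 log10 (r_i / 1 px)).  Pairs with a zero range are skipped.
    """
    reasons: dict = {}
    r = cycles.dyn_ranges()
    if r.size < 2:
        reason = "fewer than 2 cycles"
        return {"AP": np.nan, "AVI": np.nan, "mSH": np.nan, "SH": np.nan,
                "reasons": {k: reason for k in ("AP", "AVI", "mSH", "SH")}}
    valid_pair = (r[:-1] > 0) & (r[1:] > 0)
    if not valid_pair.all():
        warnings.warn("pairs with zero dynamic range skipped", stacklevel=2)
    r0, r1 = r[:-1][valid_pair], r[1:][valid_pair]
    if r0.size == 0:
        reason = "all cycle pairs have zero dynamic range"
        return {"AP": np.nan, "AVI": np.nan, "mSH": np.nan, "SH": np.nan,
                "reasons": {k: reason for k in ("AP", "AVI", "mSH", "SH")}}
    ap = float(np.mean(np.minimum(r0, r1) / np.maximum(r0, r1)))
    msh = float(np.mean(np.abs(20.0 * np.log10(r1 / r0))))
    mean_r = float(np.mean(r))
    sd_r = float(np.std(r, ddof=1))
    if sd_r > 0 and mean_r > 0:
        avi = 20.0 * np.log10(sd_r / mean_r)
    else:
        avi = np.nan
        reasons["AVI"] = "zero amplitude variability"
    rpos = r[r > 0]
    denom = float(np.mean(20.0 * np.log10(rpos)))
    if denom > 0:
        sh = 100.0 * msh / denom
    else:
        sh = np.nan
        reasons["SH"] = "non-positive mean dB dynamic range"
    return {"AP": ap, "AVI": avi, "mSH": msh, "SH": sh, "reasons": reasons}


def compute_time_perturbation(cycles: CycleSet) -> dict:
    """mJT (ms) and JT (%): mean absolute consecutive period difference and
    its ratio to the mean period."""
    T = cycles.periods()
    if T.size < 2:
        reason = "fewer than 2 cycles"
        return {"mJT": np.nan, "JT": np.nan, "reasons": {"mJT": reason, "JT": reason}}
    mjt_s = float(np.mean(np.abs(np.diff(T))))
    return {
        "mJT": mjt_s * 1000.0,
        "JT": 100.0 * mjt_s / float(np.mean(T)),
        "reasons": {},
    }


# ---------------------------------------------------------------------------
# (C) spectral noise measures
# ---------------------------------------------------------------------------

def spectral_measures(
    power: np.ndarray,
    freqs: np.ndarray,
    f0: float,
    harmonic_bw_rel: float = 0.12,
) -> dict:
    """HI, HNR, NNE and SPF from a one-sided power spectrum.

    Harmonic band k collects the bins within +-harmonic_bw_rel*F0 of k*F0,
    k = 1..floor(Nyquist/F0); E_noise is the energy of all other bins, so
    E_harm + E_noise = E_total to machine precision.

    HI = 100*E_harm/E_total and HNR = 10 log10(E_harm/E_noise) (capped at
    +-120 dB) use this band split directly.  NNE uses the estimated noise
    energy: the mean noise power density of the between-harmonic bins
    extrapolated over the whole spectrum (the noise floor continues under
    the harmonic peaks), so NNE -> 0 dB for a pure-noise signal and is
    strongly negative for a nearly periodic one.  SPF = 10 log10(GM/AM) of
    the power coefficients, DC excluded.
    """
    power = np.asarray(power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    nyquist = float(freqs[-1])
    k_max = int(np.floor(nyquist / f0))
    harm_mask = np.zeros(power.size, dtype=bool)
    for k in range(1, k_max + 1):
        harm_mask |= np.abs(freqs - k * f0) <= harmonic_bw_rel * f0
    harm_mask[0] = False  # DC excluded
    noise_mask = ~harm_mask
    noise_mask[0] = False

    e_harm = float(power[harm_mask].sum())
    e_noise = float(power[noise_mask].sum())
    e_total = e_harm + e_noise
    if e_total <= 0:
        reason = "zero spectral energy"
        return {"HI": np.nan, "HNR": np.nan, "NNE": np.nan, "SPF": np.nan,
                "E_harm": 0.0, "E_noise": 0.0,
                "reasons": {k: reason for k in ("HI", "HNR", "NNE", "SPF")}}

    hi = 100.0 * e_harm / e_total
    if e_noise <= 0:
        warnings.warn("zero noise energy; HNR capped at +120 dB", stacklevel=2)
        hnr = _DB_CAP
    elif e_harm <= 0:
        hnr = -_DB_CAP
    else:
        hnr = float(np.clip(10.0 * np.log10(e_harm / e_noise), -_DB_CAP, _DB_CAP))

    # estimated noise energy: between-harmonic density over the full spectrum
    n_bins = int(harm_mask.sum() + noise_mask.sum())
    n_noise_bins = int(noise_mask.sum())
    if n_noise_bins > 0 and e_noise > 0:
        e_noise_est = e_noise / n_noise_bins * n_bins
        nne = float(np.clip(10.0 * np.log10(e_noise_est / e_total), -_DB_CAP, _DB_CAP))
    else:
        nne = -_DB_CAP

    coeffs = power[1:]
    tiny = np.finfo(float).tiny
    log_gm = float(np.mean(np.log10(np.maximum(coeffs, tiny))))
    spf = 10.0 * (log_gm - np.log10(float(np.mean(coeffs))))
    spf = min(spf, 0.0)
    return {"HI": hi, "HNR": hnr, "NNE": nne, "SPF": spf,
            "E_harm": e_harm, "E_noise": e_noise, "reasons": {}}


def compute_spectral_noise(
    gaw: GAWRecord,
    cycles: CycleSet,
    harmonic_bw_rel: float = 0.12,
    pad_factor: int = 4,
) -> dict:
    """HI, HNR, NNE, SPF on the power spectrum of the analyzed window.

    The window spans the analyzed cycles; it is mean-removed, Hann-weighted
    and zero-padded to at least ``pad_factor`` times its length, with F0
    taken from the detected cycles.  See :func:`spectral_measures` for the
    estimator conventions.
    """
    used = cycles.used
    if len(used) < 2:
        reason = "fewer than 2 cycles"
        return {"HI": np.nan, "HNR": np.nan, "NNE": np.nan, "SPF": np.nan,
                "reasons": {k: reason for k in ("HI", "HNR", "NNE", "SPF")}}
    i0, i1 = used[0].i_start, used[-1].i_end
    x = gaw.total_area[i0:i1].astype(float)
    x = x - x.mean()
    w = hann(x.size, sym=False)
    nfft = 1
    while nfft < pad_factor * x.size:
        nfft *= 2
    coeffs = np.fft.rfft(x * w, n=nfft)
    power = np.abs(coeffs) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / gaw.fs_fps)
    f0 = 1.0 / float(np.mean([c.T for c in used]))
    out = spectral_measures(power, freqs, f0, harmonic_bw_rel)
    out.pop("E_harm", None)
    out.pop("E_noise", None)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_all(
    gaw: GAWRecord, cycles: CycleSet, config: AnalysisConfig | None = None
) -> ParameterSet:
    """Populate every parameter (or its undefined sentinel) for one GAW."""
    cfg = config or AnalysisConfig()
    out = ParameterSet(fps=gaw.fs_fps, n_cycles_used=cycles.n_used)
    for part in (
        compute_time_quotients(cycles),
        compute_amplitude_dynamics(gaw, cycles),
        compute_amplitude_perturbation(cycles),
        compute_time_perturbation(cycles),
        compute_spectral_noise(
            gaw, cycles, harmonic_bw_rel=cfg.harmonic_bw_rel, pad_factor=cfg.pad_factor
        ),
    ):
        reasons = part.pop("reasons", {})
        for name, value in part.items():
            setattr(out, name, value)
        out.reasons.update(reasons)
    return out


def analyze_gaw(gaw: GAWRecord, config: AnalysisConfig | None = None) -> ParameterSet:
    """Detect cycles and compute all 20 parameters for one GAW."""
    cfg = config or AnalysisConfig()
    cycles = detect_cycles(
        gaw, closure_threshold_rel=cfg.closure_threshold_rel, max_cycles=cfg.max_cycles
    )
    return compute_all(gaw, cycles, cfg)


def parameter_table(
    sweep: list[tuple[str, float, GAWRecord]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Analyze a rate sweep; one row per (recording, fps) with 20 parameter columns.

    A recording/rate whose analysis fails outright (e.g. no oscillation) gets
    a row of sentinels; the sweep is never aborted.
    """
    rows = []
    for rec_id, fps, gaw in sweep:
        row: dict = {"recording": rec_id, "fps": fps}
        try:
            ps = analyze_gaw(gaw, config)
            row.update({name: getattr(ps, name) for name in PARAMETER_NAMES})
            row["n_cycles_used"] = ps.n_cycles_used
        except Exception as exc:  # sentinel row, never abort the sweep
            warnings.warn(f"{rec_id}@{fps:g}fps failed: {exc}", stacklevel=2)
            row.update({name: np.nan for name in PARAMETER_NAMES})
            row["n_cycles_used"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


__all__.append("parameter_table")
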