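"""Per-mimic T1/T2 fitting, relaxivity regression, and tissue matching.

T1 is fit to signed inversion-recovery data (phase-corrected real values,
no magnitude operator) with the three-term recovery model shared with the
simulator; T2 is a single-component exponential fit to the multi-echo
spin-echo train.  Relaxation *rates* of the doped mimics are then regressed
linearly on concentration, ``R = R0 + r C``, whose slope is the relaxivity
(mM^-1 s^-1).  Mimics whose relaxation times are too short for the
protocol's shortest TI/TE are excluded before the regression through the
concentration filters C[NiCl2] < 60 mM and 0.02 < C[MnCl2] < 1 mM, plus any
explicit exclusions (e.g. a mimic reported to have drifted).

Finally, mimics are matched to tissue reference relaxation times.  Matching
uses T2 only — the QC protocol is T2-weighted, so T2 dominates the observed
contrast — and the residual T1/T2 offsets are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import ir_signal, mese_signal

#: Concentration windows (mM) inside which the mapping protocol resolves the
#: mimic relaxation times.
CONCENTRATION_FILTERS = {
    "NiCl2": lambda c: c < 60.0,
    "MnCl2": lambda c: (c > 0.02) & (c < 1.0),
}

#: Neonatal tissue reference relaxation times (seconds) used for matching.
NEONATAL_TISSUE_REFERENCES = {
    "neonatal WM": {"t1": 0.702, "t2": 0.294},
    "neonatal deep GM": {"t1": 0.364, "t2": 0.139},
}

#: MnCl2 mimic relaxation times measured at 64 mT (seconds) for the two
#: mimics bracketing neonatal WM and deep GM T2.
MNCL2_MEASURED_64MT = {4: {"t1": 0.768, "t2": 0.339}, 8: {"t1": 0.244, "t2": 0.131}}


@dataclass(frozen=True)
class RelaxFit:
    m0: float
    t_value: float  # fitted T1 or T2, seconds
    rss: float
    converged: bool
    low_confidence: bool = False


@dataclass(frozen=True)
class RelaxivityFit:
    r: float  # slope, mM^-1 s^-1
    intercept: float  # rate at zero concentration, s^-1
    stderr: float
    included_mimics: tuple[int, ...]


@dataclass(frozen=True)
class TissueMatch:
    tissue: str
    mimic_id: int
    ref_t1: float
    ref_t2: float
    mimic_t1: float
    mimic_t2: float

    @property
    def delta_t1(self) -> float:
        return self.mimic_t1 - self.ref_t1

    @property
    def delta_t2(self) -> float:
        return self.mimic_t2 - self.ref_t2


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


def fit_t1_ir(signals, tis, tr: float) -> RelaxFit:
    """Fit (M0, T1) to signed inversion-recovery signals.

    ``signals`` in arbitrary units over the inversion times ``tis``
    (seconds, strictly increasing), at repetition time ``tr``.  Nonlinear
    least squares with multi-start T1 initialization across the TI range;
    the convergence flag is honest (best effort is returned either way).
    """
    s = np.asarray(signals, dtype=float)
    ti = np.asarray(tis, dtype=float)
    if s.shape != ti.shape or s.size < 4:
        raise ValueError("need >= 4 matched (signal, TI) points")
    if np.any(np.diff(ti) <= 0):
        raise ValueError("TIs must be strictly increasing")
    if np.allclose(s, 0.0):
        raise ValueError("all-zero signal: T1 unidentifiable")

    def model(t, m0, t1):
        return ir_signal(m0, t1, t, tr)

    m0_init = float(np.max(np.abs(s)))
    best = None
    for t1_init in np.geomspace(ti[0] / 3.0, 3.0 * ti[-1], 6):
        try:
            popt, _ = curve_fit(
                model, ti, s, p0=[m0_init, t1_init],
                bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((model(ti, *popt) - s) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return RelaxFit(m0=m0_init, t_value=float(np.median(ti)), rss=float("inf"), converged=False)
    (m0, t1), rss = best
    return RelaxFit(m0=float(m0), t_value=float(t1), rss=rss, converged=True,
                    low_confidence=t1 < ti[0] / 2.0)


def fit_t2_exp(signals, tes) -> RelaxFit:
    """Fit (M0, T2) to a multi-echo spin-echo decay.

    Log-linear initialization on the positive echoes, then nonlinear
    refinement.  Flagged low-confidence when more than half the echoes are
    non-positive or the fitted T2 is below the first echo time (the protocol
    cannot resolve such fast decay).
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(tes, dtype=float)
    if s.shape != te.shape or s.size < 3:
        raise ValueError("need >= 3 matched (signal, TE) points")
    if np.any(np.diff(te) <= 0):
        raise ValueError("TEs must be strictly increasing")
    if np.ptp(s) == 0:
        raise ValueError("constant signal: T2 unidentifiable")
    pos = s > 0
    low_conf = pos.sum() <= s.size / 2

    if pos.sum() >= 2:
        slope, logm0 = np.polyfit(te[pos], np.log(s[pos]), 1)
        t2_init = -1.0 / slope if slope < 0 else te[-1]
        m0_init = float(np.exp(logm0))
    else:
        t2_init, m0_init = float(np.median(te)), float(np.max(np.abs(s)))
    t2_init = float(np.clip(t2_init, 1e-4, 100.0))

    def model(t, m0, t2):
        return mese_signal(m0, t2, t)

    try:
        popt, _ = curve_fit(
            model, te, s, p0=[max(m0_init, 1e-9), t2_init],
            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=5000,
        )
        rss = float(np.sum((model(te, *popt) - s) ** 2))
        converged = True
        m0, t2 = float(popt[0]), float(popt[1])
    except RuntimeError:
        m0, t2, rss, converged = m0_init, t2_init, float("inf"), False
    return RelaxFit(m0=m0, t_value=t2, rss=rss, converged=converged,
                    low_confidence=low_conf or t2 < te[0])


# ---------------------------------------------------------------------------
# Relaxivity regression
# ---------------------------------------------------------------------------


def apply_concentration_filter(array: str, concentrations) -> np.ndarray:
    """Boolean mask of mimics surviving the array's concentration window."""
    key = "NiCl2" if "NiCl2" in array else "MnCl2" if "MnCl2" in array else None
    if key is None:
        raise ValueError(f"no concentration filter for array {array!r}")
    return np.asarray(CONCENTRATION_FILTERS[key](np.asarray(concentrations, dtype=float)))


def fit_relaxivity(
    mimics: list[tuple[float, float]] | np.ndarray,
    array: str,
    excluded_ids: tuple[int, ...] = (),
) -> RelaxivityFit:
    """Ordinary least squares of relaxation rate on concentration.

    ``mimics`` holds (concentration mM, rate s^-1) in mimic-index order;
    the array's concentration filter and any explicit exclusions (1-based
    mimic indices) are applied first.  Slope = relaxivity, intercept = rate
    at zero concentration, with the slope's standard error.
    """
    import statsmodels.api as sm

    arr = np.asarray(mimics, dtype=float).reshape(-1, 2)
    conc, rate = arr[:, 0], arr[:, 1]
    keep = apply_concentration_filter(array, conc)
    for idx in excluded_ids:
        if not 1 <= idx <= len(conc):
            raise ValueError(f"excluded mimic index out of range: {idx}")
        keep[idx - 1] = False
    if keep.sum() < 3:
        raise ValueError("fewer than 3 mimics survive the filters")
    X = sm.add_constant(conc[keep])
    fit = sm.OLS(rate[keep], X).fit()
    included = tuple(int(i) + 1 for i in np.flatnonzero(keep))
    return RelaxivityFit(
        r=float(fit.params[1]), intercept=float(fit.params[0]),
        stderr=float(fit.bse[1]), included_mimics=included,
    )


# ---------------------------------------------------------------------------
# Tissue matching
# ---------------------------------------------------------------------------


def match_tissue_mimics(
    references: dict[str, dict[str, float]] | None = None,
    mimic_table: dict[int, dict[str, float]] | None = None,
) -> list[TissueMatch]:
    """Pick, per tissue, the mimic whose T2 is closest to the reference T2.

    Matching is by |mimic T2 - reference T2| only (ties break toward the
    lower mimic id); T1 offsets are reported but do not drive the choice.
    """
    references = references or NEONATAL_TISSUE_REFERENCES
    mimic_table = mimic_table or MNCL2_MEASURED_64MT
    if not mimic_table:
        raise ValueError("mimic table is empty")
    out = []
    for tissue, ref in references.items():
        best = min(mimic_table, key=lambda i: (abs(mimic_table[i]["t2"] - ref["t2"]), i))
        out.append(
            TissueMatch(
                tissue=tissue, mimic_id=int(best),
                ref_t1=float(ref["t1"]), ref_t2=float(ref["t2"]),
                mimic_t1=float(mimic_table[best]["t1"]), mimic_t2=float(mimic_table[best]["t2"]),
            )
        )
    return out


def extract_series(volumes, labels, feature_ids) -> dict[str, np.ndarray]:
    """Median ROI signal per feature across a mapping series of volumes."""
    out = {fid: [] for fid in feature_ids}
    for vol in volumes:
        for fid in feature_ids:
            sel = labels.feature_mask(fid)
            if not sel.any():
                raise ValueError(f"empty label for feature {fid}")
            out[fid].append(float(np.median(vol.data[sel])))
    return {fid: np.asarray(v) for fid, v in out.items()}
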