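"""OGTT-derived insulin-sensitivity and secretion indices, and lipid math.

All inputs are SI: glucose in mmol/L, insulin in pmol/L, free fatty acids
in µmol/L, lipids in mmol/L.  Index formulas that were published with
conventional units convert internally with

    insulin:  1 mU/L = 6.945 pmol/L
    glucose:  1 mmol/L = 18.016 mg/dL

The seven-point oral glucose tolerance test (OGTT) samples glucose and
insulin at minutes 0, 15, 30, 45, 60, 90 and 120; time-weighted means are
trapezoidal AUCs divided by the grid span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "OGTT_MINUTES",
    "INSULIN_PMOL_PER_MU",
    "MGDL_PER_MMOL",
    "OGTTRecord",
    "IndexPanel",
    "trapezoid_auc",
    "friedewald_ldl",
    "waist_hip_ratio",
    "homa_ir",
    "homa_beta",
    "matsuda_index",
    "hiri",
    "misi",
    "adipo_ir",
    "insulinogenic_index",
    "disposition_index",
    "index_panel",
]

OGTT_MINUTES = (0, 15, 30, 45, 60, 90, 120)
INSULIN_PMOL_PER_MU = 6.945  # pmol/L per mU/L
MGDL_PER_MMOL = 18.016  # mg/dL per mmol/L glucose
FRIEDEWALD_TG_LIMIT = 4.5  # mmol/L


class UnitDomainError(ValueError):
    """An index is requested outside its domain of validity."""


@dataclass
class OGTTRecord:
    """One subject-visit's OGTT curves and fasting biochemistry (SI units)."""

    subject_id: str
    timepoint: str
    glucose: dict[int, float]  # minute -> mmol/L
    insulin: dict[int, float]  # minute -> pmol/L
    ffa0: float | None = None  # µmol/L
    tc: float | None = None  # mmol/L
    tg: float | None = None
    hdl: float | None = None
    glp1: dict[int, float] = field(default_factory=dict)  # pmol/L

    def __post_init__(self) -> None:
        for name, curve in (("glucose", self.glucose), ("insulin", self.insulin)):
            minutes = list(curve)
            if any(m2 <= m1 for m1, m2 in zip(minutes, minutes[1:])):
                raise ValueError(f"{name} minute grid must be strictly increasing")
        if any(v <= 0 for v in self.glucose.values()):
            raise ValueError("glucose values must be positive")
        if any(v < 0 for v in self.insulin.values()):
            raise ValueError("insulin values must be non-negative")

    def grid(self, which: str, minutes: tuple[int, ...] = OGTT_MINUTES) -> np.ndarray:
        curve = getattr(self, which)
        missing = [m for m in minutes if m not in curve]
        if missing:
            raise UnitDomainError(f"{which} missing OGTT minutes {missing}")
        return np.array([curve[m] for m in minutes], dtype=float)


@dataclass
class IndexPanel:
    """The derived metabolic index panel for one subject-visit."""

    HOMA_IR: float | None = None  # dimensionless
    Matsuda: float | None = None  # dimensionless
    HIRI: float | None = None  # (mg/dL·min) × (mU/L·min)
    MISI: float | None = None  # (mmol/L/min) per (mU/L)
    ADIPO_IR: float | None = None  # mmol/L × pmol/L
    HOMA_beta: float | None = None  # %
    insulinogenic_index: float | None = None  # pmol/L per mmol/L
    disposition_index: float | None = None  # dimensionless
    LDL: float | None = None  # mmol/L

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def trapezoid_auc(times: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under a sampled curve (value·min)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 2:
        raise ValueError("need >= 2 matching (time, value) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def friedewald_ldl(tc: float, tg: float, hdl: float) -> float:
    """LDL = TC − TG/2.2 − HDL (all mmol/L); valid for TG ≤ 4.5 mmol/L."""
    if tg > FRIEDEWALD_TG_LIMIT:
        raise UnitDomainError(
            f"Friedewald formula invalid for TG > {FRIEDEWALD_TG_LIMIT} mmol/L"
        )
    return tc - tg / 2.2 - hdl


def waist_hip_ratio(waist_cm: float, hip_cm: float) -> float:
    if waist_cm <= 0 or hip_cm <= 0:
        raise ValueError("circumferences must be positive")
    return waist_cm / hip_cm


def homa_ir(g0: float, i0: float) -> float:
    """HOMA-IR = G0[mmol/L] × I0[mU/L] / 22.5 (I0 given in pmol/L)."""
    if g0 <= 0 or i0 <= 0:
        raise ValueError("fasting glucose and insulin must be positive")
    return g0 * (i0 / INSULIN_PMOL_PER_MU) / 22.5


def homa_beta(g0: float, i0: float) -> float:
    """HOMA-β = 20 × I0[mU/L] / (G0 − 3.5) (%), defined for G0 > 3.5 mmol/L."""
    if g0 <= 3.5:
        raise UnitDomainError("HOMA-beta undefined for fasting glucose <= 3.5 mmol/L")
    if i0 < 0:
        raise ValueError("fasting insulin must be non-negative")
    return 20.0 * (i0 / INSULIN_PMOL_PER_MU) / (g0 - 3.5)


def _ogtt_means(ogtt: OGTTRecord) -> tuple[float, float, float, float]:
    """Fasting and time-weighted mean glucose (mg/dL) and insulin (mU/L)."""
    t = np.array(OGTT_MINUTES, dtype=float)
    g = ogtt.grid("glucose") * MGDL_PER_MMOL
    i = ogtt.grid("insulin") / INSULIN_PMOL_PER_MU
    span = t[-1] - t[0]
    return g[0], i[0], trapezoid_auc(t, g) / span, trapezoid_auc(t, i) / span


def matsuda_index(ogtt: OGTTRecord) -> float:
    """Whole-body insulin sensitivity: 10000 / √(G0·I0·Ḡ·Ī).

    G in mg/dL and I in mU/L; Ḡ, Ī are trapezoidal OGTT means.
    """
    g0, i0, gbar, ibar = _ogtt_means(ogtt)
    prod = g0 * i0 * gbar * ibar
    if prod <= 0:
        raise UnitDomainError("Matsuda index undefined with a zero factor")
    return 10000.0 / np.sqrt(prod)


def hiri(ogtt: OGTTRecord) -> float:
    """Hepatic insulin resistance: AUC_glucose(0–30) × AUC_insulin(0–30).

    Glucose AUC in mg/dL·min, insulin AUC in mU/L·min.
    """
    t = np.array([0.0, 15.0, 30.0])
    g = ogtt.grid("glucose", (0, 15, 30)) * MGDL_PER_MMOL
    i = ogtt.grid("insulin", (0, 15, 30)) / INSULIN_PMOL_PER_MU
    return trapezoid_auc(t, g) * trapezoid_auc(t, i)


def misi(ogtt: OGTTRecord) -> float:
    """Muscle insulin sensitivity: glucose decline rate / mean insulin.

    The decline rate (mmol/L per min) is the least-squares slope magnitude
    over the grid points from the glucose peak to the subsequent nadir;
    mean insulin (mU/L) is the trapezoidal OGTT mean.  Undefined when the
    glucose peak falls on the final sample.
    """
    t = np.array(OGTT_MINUTES, dtype=float)
    g = ogtt.grid("glucose")
    peak = int(np.argmax(g))
    if peak == len(g) - 1:
        raise UnitDomainError("MISI undefined: glucose peak at the final sample")
    nadir = peak + int(np.argmin(g[peak:]))
    slope = np.polyfit(t[peak : nadir + 1], g[peak : nadir + 1], 1)[0]
    _, _, _, ibar = _ogtt_means(ogtt)
    if ibar <= 0:
        raise UnitDomainError("MISI undefined with zero mean insulin")
    return float(-slope) / ibar


def adipo_ir(ffa0_umol: float, i0: float) -> float:
    """Adipose insulin resistance: fasting FFA (mmol/L) × fasting insulin (pmol/L)."""
    if ffa0_umol < 0 or i0 < 0:
        raise ValueError("inputs must be non-negative")
    return (ffa0_umol / 1000.0) * i0


def insulinogenic_index(ogtt: OGTTRecord) -> float:
    """Early insulin secretion: (I30 − I0) / (G30 − G0), pmol/L per mmol/L."""
    g = ogtt.grid("glucose", (0, 30))
    i = ogtt.grid("insulin", (0, 30))
    if g[1] == g[0]:
        raise UnitDomainError("insulinogenic index undefined: G30 equals G0")
    return (i[1] - i[0]) / (g[1] - g[0])


def disposition_index(igi: float, matsuda: float) -> float:
    """Secretion adjusted for sensitivity: insulinogenic × Matsuda."""
    return igi * matsuda


def index_panel(ogtt: OGTTRecord) -> IndexPanel:
    """Compute every index the record's data permit; absent inputs → None."""
    panel = IndexPanel()

    def attempt(name, fn, *args):
        try:
            setattr(panel, name, float(fn(*args)))
        except (UnitDomainError, ValueError):
            pass

    g0 = ogtt.glucose.get(0)
    i0 = ogtt.insulin.get(0)
    if g0 is not None and i0 is not None:
        attempt("HOMA_IR", homa_ir, g0, i0)
        attempt("HOMA_beta", homa_beta, g0, i0)
        if ogtt.ffa0 is not None:
            attempt("ADIPO_IR", adipo_ir, ogtt.ffa0, i0)
    attempt("Matsuda", matsuda_index, ogtt)
    attempt("HIRI", hiri, ogtt)
    attempt("MISI", misi, ogtt)
    attempt("insulinogenic_index", insulinogenic_index, ogtt)
    if panel.insulinogenic_index is not None and panel.Matsuda is not None:
        panel.disposition_index = disposition_index(
            panel.insulinogenic_index, panel.Matsuda
        )
    if ogtt.tc is not None and ogtt.tg is not None and ogtt.hdl is not None:
        attempt("LDL", friedewald_ldl, ogtt.tc, ogtt.tg, ogtt.hdl)
    return panel
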