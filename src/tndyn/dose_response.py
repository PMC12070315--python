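"""Motility dose-response analytics.

The in vitro motility assay (IVMA) reports the percentage of fluorescent
thin filaments moving as a function of free [Ca2+] or of compound
concentration.  Curves are fit with a four-parameter Hill model

    y(x) = y0 + (yinf - y0) * x^h / (EC50^h + x^h)

where y0 is the response at zero dose, yinf the saturating response, h
the Hill slope and EC50 the half-effect concentration (uM).  EC50 is
optimised on a log scale.  ``floor``/``ceiling`` are reported as
min/max(y0, yinf) so they are ordered for rising and falling curves alike.

The single-point *coupling statistic* compares phosphorylated (P) and
unphosphorylated (uP) motility at a fixed [Ca2+] near the uP EC50
(default 0.075 uM).  Because phosphorylation lowers Ca2+ sensitivity, a
normally coupled filament moves less when phosphorylated at that point;
the statistic is signed so that this wild-type behaviour scores positive
(roughly +20 to +30 percentage points), i.e. delta = uP - P.  A reverse
recoupler drives the statistic negative; |delta| below a noise threshold
is classified as uncoupled.  The raw P - uP difference is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseDataset",
    "HillFit",
    "CouplingStatistic",
    "DegenerateFitError",
    "hill_curve",
    "hill_fit",
    "coupling_constant",
    "compound_dose_response",
]

DEFAULT_SINGLE_POINT_CA_UM = 0.075
UNCOUPLED_THRESHOLD = 5.0  # percentage points; well below the wild-type +20..+30 band
MIN_RESPONSE_RANGE = 5.0   # percentage points below which a fit is degenerate


class DegenerateFitError(RuntimeError):
    """Dose-response data without a resolvable transition."""


@dataclass
class DoseResponseDataset:
    """Tabulated motility points.

    ``points`` columns: compound, compound_conc_uM, ca_conc_uM, phospho
    (P/uP), replicate, pct_motile.  Responses are percentages in [0, 100];
    concentrations are non-negative.
    """

    points: pd.DataFrame
    compound: str = ""
    fixed_ca: bool = False

    REQUIRED = ("compound", "compound_conc_uM", "ca_conc_uM", "phospho", "replicate", "pct_motile")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.points.columns]
        if missing:
            raise ValueError(f"dose-response table missing columns: {missing}")
        if (self.points["compound_conc_uM"] < 0).any() or (self.points["ca_conc_uM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        resp = self.points["pct_motile"]
        if (resp < 0).any() or (resp > 100).any():
            raise ValueError("pct_motile must lie in [0, 100]")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DoseResponseDataset":
        return cls(points=pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False, float_format="%.6g")

    def subset(self, phospho: str) -> pd.DataFrame:
        return self.points[self.points["phospho"] == phospho]


@dataclass
class HillFit:
    ec50: float         # uM
    hill_slope: float   # > 0
    floor: float        # min(y0, yinf)
    ceiling: float      # max(y0, yinf)
    residual_sse: float
    response_at_zero: float
    response_at_sat: float

    @property
    def increasing(self) -> bool:
        return self.response_at_sat >= self.response_at_zero

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_curve(x, self.response_at_zero, self.response_at_sat, self.ec50, self.hill_slope)

    def to_dict(self) -> dict:
        return {
            "ec50_uM": self.ec50,
            "hill_slope": self.hill_slope,
            "floor": self.floor,
            "ceiling": self.ceiling,
            "sse": self.residual_sse,
        }


def hill_curve(x, y0: float, yinf: float, ec50: float, slope: float):
    """Four-parameter Hill curve; well-defined at x = 0 for any slope sign."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = np.power(x / ec50, slope)
        f = t / (1.0 + t)
    f = np.where(x == 0, 0.0 if slope > 0 else 1.0, f)
    f = np.nan_to_num(f, nan=1.0, posinf=1.0)
    return y0 + (yinf - y0) * f


def hill_fit(concentration: np.ndarray, response: np.ndarray) -> HillFit:
    """Unweighted least-squares Hill fit; replicate points enter individually.

    Initialisation from the data: y0/yinf from the responses at the extreme
    concentrations, EC50 at the concentration nearest half-max, slope 1.
    Raises :class:`DegenerateFitError` when fewer than 4 distinct
    concentrations are present, the response range is under 5 percentage
    points, or the optimiser fails.
    """
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentration and response must be matching 1-d arrays")
    if np.unique(x).size < 4:
        raise DegenerateFitError("need >= 4 distinct concentrations spanning the transition")
    if float(y.max() - y.min()) < MIN_RESPONSE_RANGE:
        raise DegenerateFitError(
            f"response range {y.max() - y.min():.2f} < {MIN_RESPONSE_RANGE} percentage points"
        )

    order = np.argsort(x)
    lo_mean = float(y[order[: max(1, len(x) // 4)]].mean())
    hi_mean = float(y[order[-max(1, len(x) // 4):]].mean())
    half = (lo_mean + hi_mean) / 2.0
    positive = x[x > 0]
    ec50_init = float(positive[np.argmin(np.abs(y[x > 0] - half))]) if positive.size else 1.0

    def residuals(p):
        y0, yinf, log_ec50, slope = p
        return hill_curve(x, y0, yinf, 10.0**log_ec50, slope) - y

    p0 = np.array([lo_mean, hi_mean, np.log10(ec50_init), 1.0])
    sol = least_squares(residuals, p0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise DegenerateFitError(f"Hill fit failed to converge: {sol.message}")
    y0, yinf, log_ec50, slope = sol.x
    if slope < 0:  # (y0, yinf, -h) is the same curve as (yinf, y0, +h)
        y0, yinf, slope = yinf, y0, -slope
    if slope == 0:
        raise DegenerateFitError("fitted Hill slope is zero")
    sse = float((sol.fun**2).sum())
    return HillFit(
        ec50=float(10.0**log_ec50),
        hill_slope=float(slope),
        floor=float(min(y0, yinf)),
        ceiling=float(max(y0, yinf)),
        residual_sse=sse,
        response_at_zero=float(y0),
        response_at_sat=float(yinf),
    )


@dataclass
class CouplingStatistic:
    """Single-point phosphorylation effect at a fixed [Ca2+].

    ``delta_motility`` uses the wild-type-positive convention (uP - P);
    ``raw_p_minus_up`` is the unadjusted difference.
    """

    delta_motility: float
    raw_p_minus_up: float
    ca_conc_uM: float
    classification: str  # coupled | uncoupled | reverse
    n_P: int
    n_uP: int


def _responses_at(values: pd.DataFrame | np.ndarray, ca_conc: float, label: str) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        mask = np.isclose(values["ca_conc_uM"].to_numpy(dtype=float), ca_conc, rtol=1e-6, atol=1e-12)
        resp = values.loc[mask, "pct_motile"].to_numpy(dtype=float)
    else:
        resp = np.asarray(values, dtype=float)
    if resp.size == 0:
        raise ValueError(f"{label} dataset has no responses at [Ca2+] = {ca_conc} uM")
    return resp


def coupling_constant(
    dataset_P,
    dataset_uP,
    ca_conc: float = DEFAULT_SINGLE_POINT_CA_UM,
    uncoupled_threshold: float = UNCOUPLED_THRESHOLD,
) -> CouplingStatistic:
    """Coupling statistic from the two phosphorylation states' motilities at
    one [Ca2+].  Inputs are DoseResponseDataset/DataFrame rows (matched on
    ca_conc_uM) or plain response arrays."""
    p_tab = dataset_P.points if isinstance(dataset_P, DoseResponseDataset) else dataset_P
    u_tab = dataset_uP.points if isinstance(dataset_uP, DoseResponseDataset) else dataset_uP
    resp_p = _responses_at(p_tab, ca_conc, "P")
    resp_u = _responses_at(u_tab, ca_conc, "uP")
    raw = float(resp_p.mean() - resp_u.mean())
    delta = -raw  # wild-type-positive convention
    if abs(delta) < uncoupled_threshold:
        cls = "uncoupled"
    elif delta > 0:
        cls = "coupled"
    else:
        cls = "reverse"
    return CouplingStatistic(
        delta_motility=delta,
        raw_p_minus_up=raw,
        ca_conc_uM=float(ca_conc),
        classification=cls,
        n_P=int(resp_p.size),
        n_uP=int(resp_u.size),
    )


def compound_dose_response(
    single_point_table: pd.DataFrame,
    ca_conc: float = DEFAULT_SINGLE_POINT_CA_UM,
    uncoupled_threshold: float = UNCOUPLED_THRESHOLD,
) -> tuple[HillFit, pd.DataFrame]:
    """Hill fit of the coupling statistic versus compound concentration.

    ``single_point_table`` holds single-point motilities for both phospho
    states over a sweep of compound concentrations (>= 4 including 0) at the
    fixed [Ca2+].  Returns the compound-axis Hill fit (EC50 in uM) and the
    per-concentration coupling table.
    """
    concs = np.sort(single_point_table["compound_conc_uM"].unique())
    if concs.size < 4 or concs.min() > 0:
        raise DegenerateFitError("need >= 4 compound concentrations including 0")
    rows = []
    for c in concs:
        at_c = single_point_table[single_point_table["compound_conc_uM"] == c]
        stat = coupling_constant(
            at_c[at_c["phospho"] == "P"],
            at_c[at_c["phospho"] == "uP"],
            ca_conc=ca_conc,
            uncoupled_threshold=uncoupled_threshold,
        )
        rows.append(
            {
                "compound_conc_uM": float(c),
                "coupling": stat.delta_motility,
                "raw_p_minus_up": stat.raw_p_minus_up,
                "classification": stat.classification,
            }
        )
    table = pd.DataFrame(rows)
    fit = hill_fit(table["compound_conc_uM"].to_numpy(), table["coupling"].to_numpy())
    return fit, table
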