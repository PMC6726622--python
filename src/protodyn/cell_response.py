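"""MTT viability analysis with matched controls and the differential
proton-dynamic gain statistic.

Conventions follow standard plate practice: blank wells are subtracted per
experiment, irradiated no-PS groups are normalised to media controls,
PS-incubated irradiated groups to PS dark controls, and the gain at a dose
is viability(no PS) - viability(PS) in percentage points.  Per-dose P
values use Welch's unequal-variance t-test on per-well viabilities (the
choice of test is configurable; no multiple-testing correction is applied
by default, a Holm option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

PLATE_COLUMNS = [
    "well", "absorbance", "dose_Gy", "ps_uM", "ps_present",
    "experiment_id", "is_blank",
]

VIABILITY_CAP = 1.2


@dataclass
class PlateReadout:
    """Per-well MTT absorbances with condition annotations.

    ``data`` columns: well, absorbance, dose_Gy, ps_uM, ps_present (bool),
    experiment_id, is_blank (bool).  Every irradiated condition must have
    a matched unirradiated control with the same ps_present flag in the
    same experiment; each non-blank condition needs >= 3 replicate wells
    (warn-level: validated, not silently fixed).
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"plate table missing columns: {missing}")
        df = self.data
        cells = df[~df["is_blank"]]
        for (exp, ps), grp in cells.groupby(["experiment_id", "ps_present"]):
            doses = set(grp["dose_Gy"].unique())
            if any(d > 0 for d in doses) and 0 not in doses:
                raise InputError(
                    f"experiment {exp!r}, ps_present={ps}: irradiated wells "
                    "have no matched dose-0 control"
                )

    def blank_corrected(self) -> pd.DataFrame:
        """Non-blank wells with per-experiment blank means subtracted."""
        df = self.data.copy()
        blanks = (
            df[df["is_blank"]].groupby("experiment_id")["absorbance"].mean()
        )
        df["blank"] = df["experiment_id"].map(blanks).fillna(0.0)
        df["corrected"] = df["absorbance"] - df["blank"]
        out = df[~df["is_blank"]].copy()
        if (out["corrected"] < -0.05).any():
            raise InputError("blank-corrected absorbance below -0.05 tolerance")
        return out


@dataclass
class ViabilityResult:
    """Viability per condition plus per-well values for downstream tests."""

    summary: pd.DataFrame       # experiment_id, dose_Gy, ps_present, n,
                                # viability, sem, flagged
    per_well: pd.DataFrame      # adds a per-well 'viability' column


def compute_viability(readout: PlateReadout) -> ViabilityResult:
    """Viability of each condition against its matched control.

    Mean blank-corrected absorbance divided by the mean of the matched
    unirradiated control with the same ps_present flag; SEM propagated by
    the delta method.  Viabilities above the 1.2 cap are flagged, never
    clipped.
    """
    df = readout.blank_corrected()
    ctrl_stats = {}
    for (exp, ps), grp in df[df["dose_Gy"] == 0].groupby(
        ["experiment_id", "ps_present"]
    ):
        v = grp["corrected"].to_numpy(float)
        ctrl_stats[(exp, ps)] = (v.mean(), v.var(ddof=1) if v.size > 1 else 0.0, v.size)

    rows = []
    well_frames = []
    for (exp, dose, ps), grp in df.groupby(
        ["experiment_id", "dose_Gy", "ps_present"]
    ):
        key = (exp, ps)
        if key not in ctrl_stats:
            raise InputError(
                f"no matched control for experiment {exp!r}, ps_present={ps}"
            )
        c_mean, c_var, c_n = ctrl_stats[key]
        if c_mean <= 0:
            raise InputError(f"non-positive control mean in experiment {exp!r}")
        v = grp["corrected"].to_numpy(float)
        n = v.size
        mean = v.mean()
        var = v.var(ddof=1) if n > 1 else 0.0
        viability = mean / c_mean
        # delta method for a ratio of independent means
        rel_var = (var / n) / mean**2 if mean != 0 else 0.0
        rel_var += (c_var / c_n) / c_mean**2
        sem = abs(viability) * np.sqrt(rel_var)
        rows.append({
            "experiment_id": exp, "dose_Gy": dose, "ps_present": ps,
            "n": n, "viability": viability, "sem": sem,
            "flagged": bool(viability > VIABILITY_CAP),
        })
        g = grp.copy()
        g["viability"] = g["corrected"] / c_mean
        well_frames.append(g)

    summary = pd.DataFrame(rows).sort_values(
        ["experiment_id", "dose_Gy", "ps_present"]
    ).reset_index(drop=True)
    return ViabilityResult(summary=summary,
                           per_well=pd.concat(well_frames, ignore_index=True))


@dataclass
class GainResult:
    per_dose: pd.DataFrame    # experiment_id, dose_Gy, gain_points, p_value
    mean_gain: float          # pooled over all (experiment, dose) pairs
    median_gain: float
    holm_corrected: bool = field(default=False)


def differential_gain(
    result: ViabilityResult,
    holm: bool = False,
) -> GainResult:
    """Proton-dynamic differential gain per dose, pooled across experiments.

    gain = 100 * (viability(no PS) - viability(PS)) at equal dose within
    an experiment.  P values: Welch two-sample t-test on per-well
    viabilities; reported as NaN when either arm has fewer than two wells
    (such doses were tested once only and cannot be tested statistically).
    """
    summary = result.summary
    dosed = summary[summary["dose_Gy"] > 0]
    rows = []
    for (exp, dose), grp in dosed.groupby(["experiment_id", "dose_Gy"]):
        flags = set(grp["ps_present"])
        if flags != {True, False}:
            raise InputError(
                f"experiment {exp!r}, dose {dose} Gy lacks a paired "
                "with/without-PS condition"
            )
        v_no = grp[~grp["ps_present"]]["viability"].iloc[0]
        v_ps = grp[grp["ps_present"]]["viability"].iloc[0]
        wells = result.per_well
        sel = (wells["experiment_id"] == exp) & (wells["dose_Gy"] == dose)
        w_no = wells[sel & ~wells["ps_present"]]["viability"].to_numpy(float)
        w_ps = wells[sel & wells["ps_present"]]["viability"].to_numpy(float)
        if w_no.size >= 2 and w_ps.size >= 2:
            p = float(stats.ttest_ind(w_no, w_ps, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append({
            "experiment_id": exp, "dose_Gy": dose,
            "gain_points": 100.0 * (v_no - v_ps), "p_value": p,
        })
    per_dose = pd.DataFrame(rows)
    if holm and not per_dose.empty:
        p = per_dose["p_value"].to_numpy(float)
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.sum():
            order = np.argsort(p[finite])
            m = finite.sum()
            sorted_adj = np.minimum.accumulate(
                ((m - np.arange(m)) * np.sort(p[finite]))[::-1]
            )[::-1]
            vals = np.minimum(sorted_adj, 1.0)
            tmp = np.empty(m)
            tmp[order] = vals
            adj[finite] = tmp
        per_dose["p_value"] = adj
    gains = per_dose["gain_points"].to_numpy(float)
    return GainResult(
        per_dose=per_dose,
        mean_gain=float(np.mean(gains)) if gains.size else float("nan"),
        median_gain=float(np.median(gains)) if gains.size else float("nan"),
        holm_corrected=holm,
    )


def simulate_survival(
    doses,
    lq_alpha: float,
    lq_beta: float,
    pd_coefficient: float = 0.0,
    ps_conc: float = 0.0,
    rbe: float = 1.1,
) -> np.ndarray:
    """Expected viability under a linear-quadratic model with an additive
    proton-dynamic kill term.

    S(D) = exp(-alpha*(rbe*D) - beta*(rbe*D)^2) * exp(-pd_coefficient*D*c);
    reduces to pure LQ at c = 0.
    """
    d = np.asarray(doses, dtype=float)
    for name, val in (("lq_alpha", lq_alpha), ("lq_beta", lq_beta),
                      ("pd_coefficient", pd_coefficient),
                      ("ps_conc", ps_conc), ("rbe", rbe)):
        if val < 0:
            raise InputError(f"{name} must be non-negative")
    eff = rbe * d
    return np.exp(-lq_alpha * eff - lq_beta * eff**2) * np.exp(
        -pd_coefficient * d * ps_conc
    )


def read_plates(path) -> PlateReadout:
    """Load a plate CSV with the standard column layout."""
    df = pd.read_csv(path)
    for col in ("ps_present", "is_blank"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
    return PlateReadout(df)
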