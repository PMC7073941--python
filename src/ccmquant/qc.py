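"""Quality control: adenylate energy charge and Dixon's Q outlier test.

The adenylate energy charge EC = ([ATP] + 0.5[ADP]) / ([ATP] + [ADP] + [AMP])
(Atkinson's index) reads out how completely the adenylate pool is
phosphorylated; values of roughly 0.7–0.95 indicate a physiologically intact
cell and therefore a tolerated sampling/quenching protocol.

Dixon's Q (the classic r10 statistic for 3 <= n <= 10) tests the most
suspect replicate against the data range using two-tailed critical values;
at most one value per replicate set is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quantify import FLAG_OK

__all__ = [
    "AdenylatePools",
    "DixonResult",
    "QCReport",
    "energy_charge",
    "ec_within_physiological",
    "dixon_q",
    "dixon_critical_values",
    "reject_outliers",
    "qc_report",
]

ADENYLATE_IDS = ("amp", "adp", "atp")
EC_PHYSIOLOGICAL = (0.7, 0.95)


@dataclass(frozen=True)
class AdenylatePools:
    amp: float
    adp: float
    atp: float

    def __post_init__(self):
        if self.amp < 0 or self.adp < 0 or self.atp < 0:
            raise ValidationError("adenylate concentrations must be non-negative")


def energy_charge(pools: AdenylatePools) -> float:
    """Atkinson's adenylate energy charge, in [0, 1]."""
    total = pools.amp + pools.adp + pools.atp
    if total <= 0:
        raise ValidationError("energy charge undefined for an all-zero adenylate pool")
    return (pools.atp + 0.5 * pools.adp) / total


def ec_within_physiological(ec: float, lo: float = 0.7, hi: float = 0.95) -> bool:
    """Inclusive range check against the physiological band."""
    if not 0 <= ec <= 1:
        raise ValidationError("energy charge must lie in [0, 1]")
    return lo <= ec <= hi


_CRITICAL_CACHE: dict | None = None


def dixon_critical_values() -> pd.DataFrame:
    """Packaged two-tailed critical values for the r10 statistic, n = 3..10."""
    global _CRITICAL_CACHE
    if _CRITICAL_CACHE is None:
        with resources.files("ccmquant.data").joinpath("dixon_q_critical.csv").open() as fh:
            _CRITICAL_CACHE = pd.read_csv(fh, comment="#").set_index("n")
    return _CRITICAL_CACHE


@dataclass(frozen=True)
class DixonResult:
    outlier_index: int | None  # index into the input list, None if no rejection
    q: float
    q_critical: float


def dixon_q(values, alpha: float = 0.05) -> DixonResult:
    """Dixon's r10 test on a replicate vector.

    The suspect is the end with the larger gap-to-range ratio; it is
    rejected when Q exceeds the two-tailed critical value at ``alpha``.
    A zero range yields no test (no outlier).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("Dixon's Q needs at least 3 values")
    if n > 10:
        raise ValidationError("Dixon's r10 critical values cover n <= 10 only")
    table = dixon_critical_values()
    col = f"alpha_{alpha:.2f}"
    if col not in table.columns:
        raise ValidationError(f"no critical values tabulated for alpha={alpha}")
    q_crit = float(table.at[n, col])

    order = np.argsort(x, kind="stable")
    xs = x[order]
    rng_ = xs[-1] - xs[0]
    if rng_ == 0:
        return DixonResult(None, 0.0, q_crit)
    q_low = (xs[1] - xs[0]) / rng_
    q_high = (xs[-1] - xs[-2]) / rng_
    if q_high >= q_low:
        q, suspect = q_high, order[-1]
    else:
        q, suspect = q_low, order[0]
    return DixonResult(int(suspect) if q > q_crit else None, float(q), q_crit)


def reject_outliers(
    intracellular: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply Dixon's Q per (group, metabolite) replicate vector.

    Rejected replicates get their concentration set to NaN and flag
    ``outlier``.  Returns (cleaned table, outlier ledger).  Vectors with
    fewer than 3 quantified replicates are not tested.
    """
    df = intracellular.copy()
    ledger = []
    ok = (df["flag"] == FLAG_OK) & df["conc_intracellular_M"].notna()
    for (group_id, metabolite_id), idx in df[ok].groupby(["group_id", "metabolite_id"]).groups.items():
        vals = df.loc[idx, "conc_intracellular_M"].to_numpy()
        if len(vals) < 3 or len(vals) > 10:
            continue
        res = dixon_q(vals, alpha=alpha)
        if res.outlier_index is not None:
            row = idx[res.outlier_index]
            ledger.append(
                {
                    "group_id": group_id,
                    "metabolite_id": metabolite_id,
                    "outlier_sample": df.at[row, "sample_id"],
                    "q_statistic": res.q,
                    "q_critical": res.q_critical,
                }
            )
            df.loc[row, "conc_intracellular_M"] = np.nan
            df.loc[row, "flag"] = "outlier"
    ledger_df = pd.DataFrame(
        ledger, columns=["group_id", "metabolite_id", "outlier_sample", "q_statistic", "q_critical"]
    )
    return df, ledger_df


@dataclass(frozen=True)
class QCReport:
    ec_table: pd.DataFrame  # per group: ec_mean, ec_sd, n_replicates, ec_in_range
    outlier_ledger: pd.DataFrame

    def summary_text(self) -> str:
        lines = ["Energy charge per group:"]
        for r in self.ec_table.itertuples():
            sd = "n/a" if pd.isna(r.ec_sd) else f"{r.ec_sd:.3f}"
            status = "within" if r.ec_in_range else "OUTSIDE"
            if pd.isna(r.ec_mean):
                lines.append(f"  {r.Index}: EC unavailable")
            else:
                lines.append(
                    f"  {r.Index}: EC = {r.ec_mean:.3f} +/- {sd} "
                    f"(n={r.n_replicates}, {status} physiological range)"
                )
        lines.append(f"Outliers rejected (Dixon's Q): {len(self.outlier_ledger)}")
        return "\n".join(lines)


def qc_report(
    intracellular: pd.DataFrame,
    alpha: float = 0.05,
    ec_lo: float = 0.7,
    ec_hi: float = 0.95,
) -> tuple[QCReport, pd.DataFrame]:
    """Outlier rejection followed by per-group energy-charge summary.

    Per-replicate EC is computed from that replicate's AMP/ADP/ATP (all three
    must be quantified); the group EC is the mean +/- SD over replicates.
    Groups missing an adenylate get EC marked unavailable rather than
    aborting.  Returns (report, cleaned intracellular table).
    """
    cleaned, ledger = reject_outliers(intracellular, alpha=alpha)
    ok = cleaned[(cleaned["flag"] == FLAG_OK) & cleaned["metabolite_id"].isin(ADENYLATE_IDS)]
    wide = ok.pivot_table(
        index=["group_id", "sample_id"],
        columns="metabolite_id",
        values="conc_intracellular_M",
    )
    rows = {}
    for group_id in cleaned["group_id"].unique():
        sub = wide.loc[[group_id]] if group_id in wide.index.get_level_values(0) else pd.DataFrame()
        if len(sub) and all(a in sub.columns for a in ADENYLATE_IDS):
            sub = sub.dropna(subset=list(ADENYLATE_IDS))
        else:
            sub = pd.DataFrame()
        if len(sub) == 0:
            rows[group_id] = {
                "ec_mean": np.nan, "ec_sd": np.nan, "n_replicates": 0, "ec_in_range": False,
            }
            continue
        ecs = (sub["atp"] + 0.5 * sub["adp"]) / (sub["atp"] + sub["adp"] + sub["amp"])
        mean = float(ecs.mean())
        sd = float(ecs.std(ddof=1)) if len(ecs) > 1 else np.nan
        rows[group_id] = {
            "ec_mean": mean,
            "ec_sd": sd,
            "n_replicates": int(len(ecs)),
            "ec_in_range": bool(ec_lo <= mean <= ec_hi),
        }
    ec_table = pd.DataFrame.from_dict(rows, orient="index")
    ec_table.index.name = "group_id"
    return QCReport(ec_table=ec_table, outlier_ledger=ledger), cleaned
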