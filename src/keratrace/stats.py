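"""Agreement statistics: Bland–Altman limits of agreement, Pearson
correlation, repeated-measures ANOVA with Bonferroni pairwise contrasts
against the clinical history method, and the two report tables.

Table "2" holds one row per keratometric method compared with the CHM
benchmark (bias, SD of difference, Bonferroni-adjusted paired-t p, 95%
limits of agreement, Pearson r); table "1" holds the four TCRP variants by
diameter with a per-diameter repeated-measures omnibus test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .errors import DomainError
from .formulas import TCRP_DIAMETERS, tcrp_name

__all__ = [
    "PairedComparison",
    "RMCompareResult",
    "AnalysisReport",
    "bland_altman",
    "pearson",
    "repeated_measures_compare",
    "normality_check",
    "build_report",
    "TABLE2_METHODS",
    "MODIFIED_METHODS",
]

#: Degenerate paired t tests (zero-variance nonzero difference) are reported
#: with this p-value floor instead of an exact zero.
P_FLOOR = 1e-15

#: Method columns compared against CHM, in the conventional report order.
TABLE2_METHODS: tuple[str, ...] = (
    "Km",
    "TNP",
    "EKR_4.0",
    "EKR_4.5",
    *(tcrp_name("pupil", g, d) for g in ("zone", "ring") for d in (2.0, 4.0, 6.0)),
    *(tcrp_name("apex", g, d) for g in ("zone", "ring") for d in (2.0, 4.0, 6.0)),
    "K_Haigis",
    "K_Shammas",
)
MODIFIED_METHODS: tuple[str, ...] = ("modTCRP_pupil_zone_4.0", "modTCRP_apex_zone_4.0")


@dataclass(frozen=True)
class PairedComparison:
    """Agreement of one method with the CHM benchmark."""

    method: str
    mean: float
    sd: float
    bias: float
    sd_diff: float
    p_adjusted: float | None
    loa_low: float
    loa_high: float
    pearson_r: float | None
    pearson_p: float | None
    degenerate_r: bool = False


@dataclass(frozen=True)
class RMCompareResult:
    f: float
    p: float
    p_adjusted: np.ndarray
    m: int


@dataclass
class AnalysisReport:
    table2: pd.DataFrame
    table1: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "table2": self.table2.replace({np.nan: None}).to_dict(orient="records"),
                "table1": self.table1.replace({np.nan: None}).to_dict(orient="records"),
            },
            indent=2,
        )

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1.csv", index=False)
        self.table2.to_csv(outdir / "table2.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired inputs must be equal-length 1-D arrays")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DomainError("missing pairs are not allowed")
    return x, y


def bland_altman(x, y, loa_multiplier: float = 1.96):
    """Bias, SD of differences (n−1 denominator) and 95% limits of agreement
    of paired measurements ``x − y``."""
    x, y = _paired(x, y)
    if len(x) < 2:
        raise DomainError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - loa_multiplier * sd, bias + loa_multiplier * sd


def pearson(x, y):
    """Sample Pearson correlation with the two-sided t-transform p (n−2 df)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise DomainError("need at least 3 pairs for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _pairwise_vs_reference(matrix: np.ndarray, reference_col: int, m: int) -> np.ndarray:
    n, k = matrix.shape
    out = np.empty(k)
    ref = matrix[:, reference_col]
    for j in range(k):
        if j == reference_col:
            out[j] = np.nan
            continue
        d = matrix[:, j] - ref
        sd = d.std(ddof=1)
        if sd == 0:
            raw = 1.0 if np.allclose(d, 0.0) else P_FLOOR
        else:
            raw = float(sps.ttest_rel(matrix[:, j], ref).pvalue)
            raw = max(raw, P_FLOOR)
        out[j] = min(1.0, raw * m)
    return out


def repeated_measures_compare(
    matrix, reference_col: int = 0, m: int | None = None
) -> RMCompareResult:
    """Within-subject one-way repeated-measures ANOVA across method columns,
    plus Bonferroni-adjusted paired t tests of each column against the
    reference column.

    ``m`` is the Bonferroni family size (defaults to the number of non-
    reference columns).  Columns that are all identical give F = 0, p = 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise DomainError("need >= 3 subjects and >= 2 methods")
    if np.isnan(X).any():
        raise DomainError("incomplete matrix")
    n, k = X.shape
    m = m if m is not None else k - 1

    col_means = X.mean(axis=0)
    grand = X.mean()
    ss_methods = n * ((col_means - grand) ** 2).sum()
    ss_resid = ((X - X.mean(1, keepdims=True) - col_means + grand) ** 2).sum()
    if ss_methods < 1e-24 and ss_resid < 1e-24:
        f, p = 0.0, 1.0
    else:
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "method": np.tile(np.arange(k), n),
                "value": X.ravel(),
            }
        )
        res = AnovaRM(long, depvar="value", subject="subject", within=["method"]).fit()
        f = float(res.anova_table["F Value"].iloc[0])
        p = float(res.anova_table["Pr > F"].iloc[0])
        if not np.isfinite(f):  # zero residual variance with real method effect
            f, p = np.inf, float(P_FLOOR)
    p_adj = _pairwise_vs_reference(X, reference_col, m)
    return RMCompareResult(f=f, p=p, p_adjusted=p_adj, m=m)


def normality_check(values):
    """Shapiro–Wilk statistic and p; annotation only, 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise DomainError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if v.std() == 0:
        raise DomainError("zero variance")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def build_report(
    table: pd.DataFrame,
    seed: int | None = None,
    config_hash: str | None = None,
    loa_multiplier: float = 1.96,
    alpha: float = 0.05,
) -> AnalysisReport:
    """Assemble the full agreement report from a cohort table.

    The table must carry ``post_CHM`` and every ``post_<method>`` column of
    the report layout.  Table-2 rows: the CHM reference row first, the 18
    standard methods, then the two modified-TCRP rows; Bonferroni family
    size = number of methods tested (20).
    """
    needed = ["post_CHM"] + [f"post_{m}" for m in TABLE2_METHODS + MODIFIED_METHODS]
    needed += [
        f"post_{tcrp_name(c, g, d)}"
        for c in ("pupil", "apex")
        for g in ("zone", "ring")
        for d in TCRP_DIAMETERS
    ]
    for col in needed:
        if col not in table.columns:
            raise DomainError(f"missing required column {col!r}")
        if table[col].isna().any():
            raise DomainError(f"column {col!r} contains missing values")
    chm_vals = table["post_CHM"].to_numpy(dtype=float)
    methods = list(TABLE2_METHODS) + list(MODIFIED_METHODS)
    m_comp = len(methods)

    matrix = np.column_stack(
        [chm_vals] + [table[f"post_{m}"].to_numpy(dtype=float) for m in methods]
    )
    omnibus = repeated_measures_compare(matrix, reference_col=0, m=m_comp)

    rows = [
        PairedComparison(
            method="CHM",
            mean=float(chm_vals.mean()),
            sd=float(chm_vals.std(ddof=1)),
            bias=0.0,
            sd_diff=0.0,
            p_adjusted=None,
            loa_low=0.0,
            loa_high=0.0,
            pearson_r=None,
            pearson_p=None,
            degenerate_r=True,
        )
    ]
    for j, name in enumerate(methods):
        vals = matrix[:, j + 1]
        bias, sd_diff, lo, hi = bland_altman(vals, chm_vals, loa_multiplier)
        diff = vals - chm_vals
        if diff.std() == 0 or vals.std() == 0:
            r = p_r = None
            degenerate = True
        else:
            r, p_r = pearson(vals, chm_vals)
            degenerate = False
        rows.append(
            PairedComparison(
                method=name,
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)),
                bias=bias,
                sd_diff=sd_diff,
                p_adjusted=float(omnibus.p_adjusted[j + 1]),
                loa_low=lo,
                loa_high=hi,
                pearson_r=r,
                pearson_p=p_r,
                degenerate_r=degenerate,
            )
        )
    table2 = pd.DataFrame([r.__dict__ for r in rows])

    variants = [tcrp_name(c, g, 0).rsplit("_", 1)[0] for c in ("pupil", "apex") for g in ("zone", "ring")]
    t1_rows = []
    for d in TCRP_DIAMETERS:
        cols = {v: table[f"post_{v}_{d:.1f}"].to_numpy(dtype=float) for v in variants}
        X = np.column_stack(list(cols.values()))
        rm = repeated_measures_compare(X, reference_col=0, m=len(variants) - 1)
        row = {"diameter_mm": d}
        for v, vals in cols.items():
            row[f"{v}_mean"] = float(vals.mean())
            row[f"{v}_sd"] = float(vals.std(ddof=1))
        row["F"] = rm.f
        row["p"] = rm.p
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    metadata = {
        "n": int(len(table)),
        "seed": seed,
        "config_hash": config_hash,
        "m_comparisons": m_comp,
        "reference": "CHM",
        "omnibus_F": omnibus.f,
        "omnibus_p": omnibus.p,
        "loa_multiplier": loa_multiplier,
        "alpha": alpha,
    }
    return AnalysisReport(table2=table2, table1=table1, metadata=metadata)
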