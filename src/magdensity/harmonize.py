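"""Cross-scanner agreement statistics and leave-one-out linear calibration.

Agreement between paired per-breast density values from two scanners is
summarized by the mean signed difference (former - latter), a paired
two-tailed t-test, Pearson correlation, and Bland-Altman bias with 95%
limits of agreement (bias +/- 1.96 x sd of the differences).  Inter-scanner
bias is removed by an ordinary-least-squares linear map fitted under
leave-one-out cross-validation so that no unit's own data enters the model
applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DomainError,
    InsufficientFoldsError,
    PairingError,
    RankError,
)

__all__ = [
    "AgreementReport",
    "CalibrationModel",
    "paired_stats",
    "fit_calibration",
    "loo_calibrate",
    "study_report",
    "simulate_offset_cohort",
]

KEY_COLS = ["subject_id", "side"]


@dataclass(frozen=True)
class AgreementReport:
    """Pairwise agreement between two scanners' density values."""

    former: str
    latter: str
    n: int
    mean_delta: float
    t_stat: float
    p_value: float
    pearson_r: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    zero_variance: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map target = slope x source + intercept for one CV fold."""

    slope: float
    intercept: float
    n_train: int
    fold: str = ""
    source_scanner: str = ""
    target_scanner: str = ""

    def apply(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def paired_stats(
    former, latter, former_name: str = "former", latter_name: str = "latter"
) -> AgreementReport:
    """Agreement statistics for matched value sequences (former vs latter).

    The t statistic is mean(d) / (sd(d)/sqrt(n)) on the paired differences
    d = former - latter with n-1 degrees of freedom; limits of agreement are
    bias +/- 1.96 sd(d).  Zero-variance differences (identical sequences)
    are flagged and reported with t = 0 and an undefined p-value.
    """
    x = np.asarray(former, dtype=float)
    y = np.asarray(latter, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired sequences differ: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise PairingError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    zero_var = sd == 0.0
    if zero_var:
        t_stat, p_value = 0.0, float("nan")
    else:
        t_stat = bias / (sd / np.sqrt(n))
        p_value = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    if x.std() == 0.0 or y.std() == 0.0:
        r = float("nan")
        zero_var = True
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return AgreementReport(
        former=former_name,
        latter=latter_name,
        n=n,
        mean_delta=bias,
        t_stat=float(t_stat),
        p_value=float(p_value),
        pearson_r=r,
        ba_bias=bias,
        ba_loa_low=bias - 1.96 * sd,
        ba_loa_high=bias + 1.96 * sd,
        zero_variance=zero_var,
    )


def fit_calibration(
    source,
    target,
    *,
    fold: str = "",
    source_scanner: str = "",
    target_scanner: str = "",
) -> CalibrationModel:
    """Ordinary least squares of target on source (slope, intercept)."""
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired sequences differ: {x.shape} vs {y.shape}")
    if x.size < 2 or np.unique(x).size < 2:
        raise RankError("need >= 2 distinct source values")
    xm, ym = x.mean(), y.mean()
    slope = float(np.dot(x - xm, y - ym) / np.dot(x - xm, x - xm))
    intercept = float(ym - slope * xm)
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        n_train=x.size,
        fold=fold,
        source_scanner=source_scanner,
        target_scanner=target_scanner,
    )


def _as_table(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "side": r.side,
                    "scanner": r.scanner,
                    "magdensity_percent": r.magdensity,
                }
                for r in records
            ]
        )
    if "magdensity_percent" not in df.columns and "magdensity" in df.columns:
        df = df.rename(columns={"magdensity": "magdensity_percent"})
    missing = [c for c in KEY_COLS + ["magdensity_percent"] if c not in df.columns]
    if missing:
        raise ConfigError(f"density table missing columns: {missing}")
    return df


def loo_calibrate(
    records_source,
    records_target,
    unit: str = "subject",
) -> tuple[pd.DataFrame, list[CalibrationModel]]:
    """Leave-one-out linear calibration of source-scanner values onto the
    target scanner's scale.

    For each held-out unit (a whole subject by default, so both breasts of
    one person leave the training set together; ``unit='breast'`` holds out
    single (subject, side) rows), an OLS map is fitted on all remaining
    matched pairs and applied to the held-out source values.  Returns the
    calibrated table (with a ``fold`` column naming the held-out unit) and
    the per-fold models.
    """
    if unit not in ("subject", "breast"):
        raise ConfigError(f"unit must be 'subject' or 'breast', got {unit!r}")
    src = _as_table(records_source)
    tgt = _as_table(records_target)
    merged = src.merge(
        tgt[KEY_COLS + ["magdensity_percent"]],
        on=KEY_COLS,
        suffixes=("_source", "_target"),
    )
    if len(merged) != len(src) or len(merged) != len(tgt):
        raise PairingError("source and target tables do not cover the same keys")
    if unit == "subject":
        merged["_unit"] = merged["subject_id"]
    else:
        merged["_unit"] = merged["subject_id"] + "/" + merged["side"]
    units = sorted(merged["_unit"].unique())
    if len(units) < 3:
        raise InsufficientFoldsError(f"need >= 3 units, got {len(units)}")

    out_rows = []
    models = []
    src_scanner = str(src["scanner"].iloc[0]) if "scanner" in src.columns else ""
    tgt_scanner = str(tgt["scanner"].iloc[0]) if "scanner" in tgt.columns else ""
    for u in units:
        held = merged["_unit"] == u
        train = merged[~held]
        model = fit_calibration(
            train["magdensity_percent_source"],
            train["magdensity_percent_target"],
            fold=u,
            source_scanner=src_scanner,
            target_scanner=tgt_scanner,
        )
        models.append(model)
        for _, row in merged[held].iterrows():
            out_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "side": row["side"],
                    "scanner": f"{src_scanner}_calibrated" if src_scanner else "calibrated",
                    "magdensity_percent": float(
                        model.apply(row["magdensity_percent_source"])
                    ),
                    "fold": u,
                }
            )
    calibrated = pd.DataFrame(out_rows).sort_values(KEY_COLS).reset_index(drop=True)
    return calibrated, models


REQUIRED_SCANNERS = ("prisma", "mmr", "signa")


def study_report(
    density_table: pd.DataFrame,
    *,
    unit: str = "subject",
    calibration_source: str = "signa",
    calibration_target: str = "mmr",
) -> dict:
    """Full cross-scanner agreement report for the three-scanner study.

    Emits pairwise agreement (mmr vs prisma, mmr vs signa, prisma vs signa)
    before calibration; then calibrates the Signa values onto the mMR scale
    by leave-one-out OLS (a single calibration pathway, justified by the
    absence of a significant Siemens-Siemens difference) and reports both
    Siemens scanners against the calibrated Signa values.
    """
    df = _as_table(density_table)
    if "scanner" not in df.columns:
        raise ConfigError("density table must have a 'scanner' column")
    present = set(df["scanner"].unique())
    missing = [s for s in REQUIRED_SCANNERS if s not in present]
    if missing:
        raise ConfigError(f"density table missing scanners: {missing}")

    wide = (
        df.pivot_table(
            index=KEY_COLS, columns="scanner", values="magdensity_percent"
        )
        .reset_index()
        .sort_values(KEY_COLS)
    )
    if wide[list(REQUIRED_SCANNERS)].isna().any().any():
        raise PairingError("scanners do not cover the same (subject, side) keys")

    pre = {
        "mmr_vs_prisma": paired_stats(wide["mmr"], wide["prisma"], "mmr", "prisma"),
        "mmr_vs_signa": paired_stats(wide["mmr"], wide["signa"], "mmr", "signa"),
        "prisma_vs_signa": paired_stats(
            wide["prisma"], wide["signa"], "prisma", "signa"
        ),
    }

    src = df[df["scanner"] == calibration_source]
    tgt = df[df["scanner"] == calibration_target]
    calibrated, models = loo_calibrate(src, tgt, unit=unit)
    cal = wide[KEY_COLS].merge(calibrated, on=KEY_COLS)["magdensity_percent"]
    post = {
        "mmr_vs_signa_calibrated": paired_stats(
            wide["mmr"], cal, "mmr", "signa_calibrated"
        ),
        "prisma_vs_signa_calibrated": paired_stats(
            wide["prisma"], cal, "prisma", "signa_calibrated"
        ),
    }
    return {
        "pre_calibration": pre,
        "post_calibration": post,
        "calibrated_table": calibrated,
        "calibration_models": models,
        "n_breasts": int(len(wide)),
    }


def simulate_offset_cohort(
    n_subjects: int,
    offset: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    base_range: tuple[float, float] = (40.0, 80.0),
    slope: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular two-scanner cohort with a known affine offset between them.

    Source ("signa"-like) per-breast densities are drawn uniformly from
    ``base_range``; target ("mmr"-like) values are
    ``slope x source + offset + N(0, noise_sd)``.  Used to exercise the
    agreement and calibration machinery without image simulation.
    """
    if n_subjects < 2:
        raise DomainError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    rows_s, rows_t = [], []
    for i in range(n_subjects):
        for side in ("L", "R"):
            x = rng.uniform(*base_range)
            y = slope * x + offset + rng.normal(0.0, noise_sd)
            sid = f"S{i + 1:02d}"
            rows_s.append(
                {"subject_id": sid, "side": side, "scanner": "signa",
                 "magdensity_percent": x}
            )
            rows_t.append(
                {"subject_id": sid, "side": side, "scanner": "mmr",
                 "magdensity_percent": y}
            )
    return pd.DataFrame(rows_s), pd.DataFrame(rows_t)
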