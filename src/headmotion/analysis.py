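"""Session- and cohort-level statistics on motion scores.

Per-sequence motion scores feed three downstream analyses: a longitudinal
random-intercept linear mixed model of motion versus time in the scanner
(with BMI, age, sex and their time interactions), paired correlations
between an early reference sequence and later scan bins (is one measurement
predictive of the rest of the session?), and correlations of motion with
per-scan image-quality metrics. Estimation of the mixed model delegates to
statsmodels; the contract here is the design matrix — centred covariates,
female-reference sex coding, the three time interactions — and the
reporting surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .geometry import BallModel
from .metrics import motion_score
from .trace import MotionTrace, SequenceTable, annotate

__all__ = [
    "LMEFit",
    "FIXED_EFFECT_NAMES",
    "score_session",
    "fit_session_lme",
    "proxy_correlation",
    "quality_correlation",
    "wilcoxon_signed_rank",
    "percent_of_mean",
]

#: Fixed effects of the longitudinal model, in design order.
FIXED_EFFECT_NAMES = ("intercept", "time", "bmi", "age", "sex_male",
                      "time_bmi", "time_age", "time_sex_male")

_FORMULA = ("motion ~ time + bmi_centered + age_centered + sex"
            " + time:bmi_centered + time:age_centered + time:sex")
_TERM_MAP = {
    "intercept": "Intercept",
    "time": "time",
    "bmi": "bmi_centered",
    "age": "age_centered",
    "sex_male": "sex[T.male]",
    "time_bmi": "time:bmi_centered",
    "time_age": "time:age_centered",
    "time_sex_male": "time:sex[T.male]",
}


@dataclass
class LMEFit:
    """Estimates of the random-intercept longitudinal model."""

    estimates: dict
    std_errors: dict
    z_scores: dict
    random_intercept_var: float
    residual_var: float
    converged: bool
    n_subjects: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "std_errors": self.std_errors,
            "z_scores": self.z_scores,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }


def score_session(trace: MotionTrace, table: SequenceTable,
                  ball: BallModel) -> pd.DataFrame:
    """One motion score per scan sequence; break intervals are excluded.

    Sequences with too few samples for the scoring resampler are reported
    with a missing (NaN) score rather than zero. Output is invariant to the
    row order of the table (sorted by sequence start).
    """
    rows = []
    for name, start, end in sorted(table.rows(), key=lambda r: r[1]):
        try:
            score = motion_score(trace, (start, end), ball)
            rows.append({"sequence": name, "score_mm_per_s": score.value,
                         "n_seconds": score.n_seconds_used})
        except ValueError:
            rows.append({"sequence": name, "score_mm_per_s": np.nan,
                         "n_seconds": 0})
    return pd.DataFrame(rows, columns=["sequence", "score_mm_per_s",
                                       "n_seconds"])


def _check_design(data: pd.DataFrame) -> None:
    male = (data["sex"].astype(str) == "male").astype(float).to_numpy()
    X = np.column_stack([
        np.ones(len(data)),
        data["time"].to_numpy(float),
        data["bmi_centered"].to_numpy(float),
        data["age_centered"].to_numpy(float),
        male,
        data["time"].to_numpy(float) * data["bmi_centered"].to_numpy(float),
        data["time"].to_numpy(float) * data["age_centered"].to_numpy(float),
        data["time"].to_numpy(float) * male,
    ])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(FIXED_EFFECT_NAMES[j] for j in piv[rank:])
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def fit_session_lme(samples: pd.DataFrame, *, reml: bool = True) -> LMEFit:
    """Fit the longitudinal random-intercept model.

        motion ~ time + BMI_c + age_c + sex + time:BMI_c + time:age_c + time:sex
        + (1 | subject)

    ``time`` is minutes from the first acquisition, ``motion`` mm/s, BMI and
    age centred, sex coded with female as reference. REML by default.
    """
    required = {"subject_id", "time", "motion", "bmi_centered",
                "age_centered", "sex"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if samples["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    counts = samples.groupby("subject_id").size()
    if (counts < 2).any():
        raise ValueError("every subject needs at least 2 time points")
    data = samples.copy()
    data["sex"] = pd.Categorical(data["sex"].astype(str),
                                 categories=["female", "male"])
    _check_design(data)
    model = smf.mixedlm(_FORMULA, data, groups=data["subject_id"])
    fit = model.fit(reml=reml)
    est, se, z = {}, {}, {}
    for name, term in _TERM_MAP.items():
        est[name] = float(fit.fe_params[term])
        se[name] = float(fit.bse_fe[term])
        z[name] = float(est[name] / se[name]) if se[name] > 0 else np.nan
    return LMEFit(
        estimates=est, std_errors=se, z_scores=z,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        converged=bool(fit.converged),
        n_subjects=int(samples["subject_id"].nunique()),
        n_obs=int(len(samples)),
    )


def percent_of_mean(coefficient: float, samples: pd.DataFrame) -> float:
    """Report a coefficient as percent of the grand-mean motion level."""
    return 100.0 * coefficient / float(samples["motion"].mean())


def proxy_correlation(reference_scores: pd.Series,
                      later_scores: pd.DataFrame,
                      min_available: float = 0.9) -> pd.DataFrame:
    """Paired Pearson correlation of an early reference score with later bins.

    ``reference_scores`` is one scalar per subject; ``later_scores`` has one
    row per subject and one column per time bin. Bins in which fewer than
    ``min_available`` of the subjects have a value are discarded; within a
    bin, subjects with a missing value are dropped pairwise.
    """
    later = later_scores.loc[reference_scores.index]
    rows = []
    for col in later.columns:
        y = later[col]
        if y.notna().mean() < min_available:
            continue
        mask = y.notna() & reference_scores.notna()
        x, yv = reference_scores[mask], y[mask]
        if len(x) < 3 or x.std() == 0 or yv.std() == 0:
            rows.append({"bin": col, "r": np.nan, "p": np.nan,
                         "n": int(mask.sum())})
            continue
        r, p = stats.pearsonr(x, yv)
        rows.append({"bin": col, "r": float(r), "p": float(p),
                     "n": int(mask.sum())})
    return pd.DataFrame(rows, columns=["bin", "r", "p", "n"])


def quality_correlation(scores: pd.Series,
                        qc_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-scan motion scores with image-quality
    metrics (one column per metric), matched on the scan identifier index.

    Missing pairs are dropped listwise per metric; a constant metric has no
    defined correlation and is reported as missing.
    """
    common = scores.index.intersection(qc_table.index)
    s = scores.loc[common]
    rows = []
    for col in qc_table.columns:
        m = qc_table.loc[common, col]
        mask = m.notna() & s.notna()
        x, y = s[mask], m[mask]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            rows.append({"metric": col, "r": np.nan, "p": np.nan,
                         "n": int(mask.sum())})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"metric": col, "r": float(r), "p": float(p),
                     "n": int(mask.sum())})
    return pd.DataFrame(rows, columns=["metric", "r", "p", "n"])


def wilcoxon_signed_rank(x, y, *, zero_method: str = "wilcox"):
    """Paired Wilcoxon signed-rank test (exact for small samples).

    Used for paired method contrasts (e.g. per-session MTDs of two
    registration variants). Returns ``(statistic, p_value)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = stats.wilcoxon(x, y, zero_method=zero_method,
                         method="exact" if x.size <= 25 else "auto")
    return float(res.statistic), float(res.pvalue)
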