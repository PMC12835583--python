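"""Cohort-level statistics: group summaries, nonparametric comparisons,
model-vs-clinical agreement tests, and phenotype separability by LDA.

Model parameters and simulated PV-loop metrics are compared across
pulmonary-hypertension phenotypes with a Kruskal-Wallis omnibus test
followed by Dunn's pairwise z-tests (multiplicity-adjusted); paired t-tests
check agreement between model-derived and clinically measured metrics
(significance here flags *disagreement*); and linear discriminant analysis
with leave-one-out accuracy quantifies how well clinical, model-derived, or
combined feature sets separate the phenotype groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "LDAResult",
    "GroupTestResult",
    "CLINICAL_FEATURES",
    "MODEL_FEATURES",
    "build_feature_table",
    "cohort_feature_frame",
    "lda_separability",
    "group_tests",
    "dunn_test",
    "model_vs_clinical_ttest",
]

log = logging.getLogger(__name__)

#: Routine hemodynamic columns available without modeling.
CLINICAL_FEATURES = ("HR", "CO", "PAWP", "mPAP", "sPAP", "dPAP")

#: Model-derived columns: calibrated parameter subvector plus simulated
#: PV-loop metrics (goodness-of-fit diagnostics are appended when present).
MODEL_FEATURES = (
    "Rval_T", "R_PA", "R_PC", "R_PV", "C_PA", "Emax", "Emin", "tmax", "tmin",
    "EDV", "ESV", "SV", "EDP", "ESP", "SW_J",
)


@dataclass
class FeatureTable:
    """Per-patient feature matrix with phenotype labels and provenance."""

    X: pd.DataFrame
    labels: pd.Series
    selector: str
    feature_names: tuple

    @property
    def n_classes(self) -> int:
        return self.labels.nunique()

    def zscored(self) -> pd.DataFrame:
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            zero = list(self.X.columns[sd == 0])
            raise ValueError(f"zero-variance feature columns: {zero}")
        return (self.X - mu) / sd


def cohort_feature_frame(patients, metrics_by_id: dict,
                         theta_by_id: dict | None = None) -> pd.DataFrame:
    """Assemble one row per virtual patient from summaries, PV metrics and
    (optionally) calibrated parameters; defaults to ground-truth parameters
    when no calibration is supplied."""
    rows = []
    for pt in patients:
        s = pt.summary
        row = {"id": pt.id, "phenotype": pt.phenotype,
               "HR": s.HR, "CO": s.CO, "PAWP": s.PAWP, "mPAP": s.mPAP,
               "sPAP": s.sPAP, "dPAP": s.dPAP}
        src = (theta_by_id or {}).get(pt.id)
        p = pt.truth if src is None else src
        for n in ("Rval_T", "R_PA", "R_PC", "R_PV", "C_PA",
                  "Emax", "Emin", "tmax", "tmin"):
            row[n] = getattr(p, n) if not isinstance(p, dict) else p[n]
        m = metrics_by_id[pt.id]
        row.update({"EDV": m.EDV, "ESV": m.ESV, "SV": m.SV,
                    "EDP": m.EDP, "ESP": m.ESP, "SW_J": m.SW_J})
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def build_feature_table(frame: pd.DataFrame, selector: str = "combined",
                        label_column: str = "phenotype") -> FeatureTable:
    """Select the clinical, model-derived, or combined feature columns.

    Rows with missing values in the selected columns are dropped with a
    warning (e.g. patients whose calibration failed).
    """
    if selector == "clinical":
        cols = [c for c in CLINICAL_FEATURES if c in frame.columns]
    elif selector == "model":
        cols = [c for c in frame.columns
                if c in MODEL_FEATURES or c.startswith("R2_")]
    elif selector == "combined":
        cols = [c for c in frame.columns
                if c in CLINICAL_FEATURES or c in MODEL_FEATURES
                or c.startswith("R2_")]
    else:
        raise ValueError(f"unknown selector {selector!r}")
    if not cols:
        raise ValueError(f"no feature columns found for selector {selector!r}")
    X = frame[cols].astype(float)
    ok = X.notna().all(axis=1)
    if not ok.all():
        log.warning("dropping %d rows with missing features: %s",
                    (~ok).sum(), list(frame.index[~ok]))
    return FeatureTable(X=X[ok], labels=frame.loc[ok, label_column],
                        selector=selector, feature_names=tuple(cols))


@dataclass
class LDAResult:
    """2-D discriminant projection with leave-one-out accuracy."""

    projection: pd.DataFrame          # columns LD1, LD2 (LD2 zero if 2 classes)
    loo_accuracy: float
    centroids: pd.DataFrame
    selector: str
    shrinkage: str | float = "auto"
    scalings: np.ndarray = field(default=None, repr=False)


def _lda(shrinkage):
    return LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)


def lda_separability(ft: FeatureTable, seed: int | None = None,
                     shrinkage: str | float = "auto") -> LDAResult:
    """Fit shrinkage-regularized LDA and score leave-one-out accuracy.

    Pooled-covariance LDA with Ledoit-Wolf shrinkage (solver='eigen')
    keeps the problem well-posed when features rival the sample count.
    Standardization is fit inside each LOO fold to avoid leakage.
    """
    counts = ft.labels.value_counts()
    if ft.n_classes < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 members each")
    Xz = ft.zscored().to_numpy()
    y = ft.labels.to_numpy()
    try:
        lda = _lda(shrinkage).fit(Xz, y)
    except np.linalg.LinAlgError:
        # tiny cohorts can defeat the data-driven shrinkage estimate;
        # fall back to a fixed heavy shrinkage
        shrinkage = 0.5
        log.warning("pooled covariance not positive definite under "
                    "auto-shrinkage; refitting with lambda=%.2f", shrinkage)
        lda = _lda(shrinkage).fit(Xz, y)
    Z = lda.transform(Xz)
    n_axes = min(2, Z.shape[1])
    proj = pd.DataFrame(0.0, index=ft.X.index, columns=["LD1", "LD2"])
    proj.iloc[:, :n_axes] = Z[:, :n_axes]
    pipe = make_pipeline(StandardScaler(), _lda(shrinkage))
    acc = cross_val_score(pipe, ft.X.to_numpy(), y, cv=LeaveOneOut()).mean()
    cent = proj.groupby(ft.labels).mean()
    return LDAResult(projection=proj, loo_accuracy=float(acc),
                     centroids=cent, selector=ft.selector,
                     shrinkage=shrinkage, scalings=lda.scalings_)


@dataclass
class GroupTestResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons."""

    H: float
    p_value: float
    dunn: pd.DataFrame            # pair, z, p_raw, p_adj, significant
    groups: tuple
    defined: bool = True


def dunn_test(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after a Kruskal-Wallis omnibus.

    Uses the pooled mean-rank statistic with tie correction; p-values are
    multiplicity-adjusted ('holm', 'bonferroni', or None).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(values)
    N = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    i = 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[i:i + len(v)].mean()
        i += len(v)
    # tie correction to the rank variance
    _, counts = np.unique(all_vals, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            na, nb = len(values[a]), len(values[b])
            se = np.sqrt((N * (N + 1) / 12.0 - tie) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"pair": f"{ga} vs {gb}", "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust is None or adjust == "none":
        df["p_adj"] = df["p_raw"]
    else:
        df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    df["significant"] = df["p_adj"] < 0.05
    return df


def group_tests(groups: dict, adjust: str = "holm") -> GroupTestResult:
    """Kruskal-Wallis H (tie-corrected) with post hoc Dunn comparisons.

    ``groups`` maps group name -> 1-D array of values.  With all values
    identical across the cohort the H statistic is undefined and reported
    as such (H = NaN, defined=False).
    """
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    all_vals = np.concatenate(values)
    if np.all(all_vals == all_vals[0]):
        return GroupTestResult(H=np.nan, p_value=np.nan,
                               dunn=pd.DataFrame(), groups=tuple(groups),
                               defined=False)
    H, p = stats.kruskal(*values)
    return GroupTestResult(H=float(H), p_value=float(p),
                           dunn=dunn_test(groups, adjust=adjust),
                           groups=tuple(groups))


def model_vs_clinical_ttest(model: np.ndarray, clinical: np.ndarray) -> dict:
    """Paired two-sample t-test on model − clinical differences.

    Under this design a *significant* p-value (< 0.05) indicates poor
    agreement between model predictions and clinical measurements.
    Zero-variance, zero-mean differences are reported as exact agreement
    (no test performed).
    """
    model = np.asarray(model, dtype=float)
    clinical = np.asarray(clinical, dtype=float)
    if model.shape != clinical.shape or model.ndim != 1:
        raise ValueError("paired arrays of equal length required")
    n = len(model)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    d = model - clinical
    if np.all(d == 0.0):
        return {"t": np.nan, "df": n - 1, "p": np.nan, "n": n,
                "mean_diff": 0.0, "exact_agreement": True}
    t, p = stats.ttest_rel(model, clinical)
    return {"t": float(t), "df": n - 1, "p": float(p), "n": n,
            "mean_diff": float(d.mean()), "exact_agreement": False}
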