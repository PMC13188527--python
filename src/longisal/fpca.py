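"""Trajectory-shape analysis: per-OTU functional PCA of CLR trajectories
with missing visits, 99%-variance component selection, and per-genotype
lasso-logistic prediction of endpoint diagnosis from the fPC scores.

Each (mouse, OTU) pair yields a 6-vector of CLR abundances over the week
grid, possibly with missing entries; trajectories are centered (observed
mean removed) so only the *shape* of the trajectory, not its level, enters
the analysis.  The covariance across weeks is estimated from
pairwise-complete products, projected to the positive-semidefinite cone by
eigenvalue clipping, and eigendecomposed; scores are best linear predictors
given the observed entries, which reduces to classical PCA scores on
complete data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TrajectoryMatrix:
    """Centered CLR trajectories per (mouse, OTU) on the week grid."""

    data: np.ndarray  # (n_mice, n_otus, n_weeks), NaN = missing
    mice: list
    otus: list
    weeks: tuple
    centering_record: np.ndarray  # (n_mice, n_otus) removed means
    mouse_meta: pd.DataFrame | None = None  # genotype/sex/diagnosis per mouse

    def trajectories(self, otu: str) -> np.ndarray:
        return self.data[:, self.otus.index(otu), :]


def build_trajectories(clr, meta: pd.DataFrame) -> TrajectoryMatrix:
    """Assemble centered trajectories from a CLR matrix and sample metadata.

    Mice observed at fewer than 2 weeks are excluded with a warning.
    """
    values = clr.values if not isinstance(clr, pd.DataFrame) else clr
    if not isinstance(values, pd.DataFrame):
        raise TypeError("clr must be a ClrMatrix or DataFrame")
    meta = meta.loc[values.index]
    weeks = tuple(sorted(meta["week"].unique()))
    week_pos = {w: j for j, w in enumerate(weeks)}
    counts = meta.groupby("mouse_id")["week"].nunique()
    mice = [m for m in dict.fromkeys(meta["mouse_id"]) if counts[m] >= 2]
    dropped = sorted(set(meta["mouse_id"]) - set(mice))
    if dropped:
        warnings.warn(f"excluded {len(dropped)} mice with < 2 visits: {dropped[:5]}")
    mouse_pos = {m: i for i, m in enumerate(mice)}
    otus = list(values.columns)

    data = np.full((len(mice), len(otus), len(weeks)), np.nan)
    for sid, row in meta.iterrows():
        if row["mouse_id"] in mouse_pos:
            data[mouse_pos[row["mouse_id"]], :, week_pos[row["week"]]] = values.loc[
                sid
            ].to_numpy()

    centering = np.nanmean(data, axis=2)
    data = data - centering[:, :, None]

    mouse_meta = (
        meta.drop_duplicates("mouse_id")
        .set_index("mouse_id")[["genotype", "sex", "diagnosis"]]
        .loc[mice]
    )
    return TrajectoryMatrix(
        data=data,
        mice=mice,
        otus=otus,
        weeks=weeks,
        centering_record=centering,
        mouse_meta=mouse_meta,
    )


class TrajectoryFPCA:
    """Functional PCA of one OTU's centered trajectories.

    Parameters
    ----------
    X
        (n_trajectories, n_weeks) matrix, NaN marking missing visits.
    weeks
        Week grid labels.
    """

    def __init__(self, X, weeks=None):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] < 10:
            raise ValueError("need >= 10 trajectories")
        self.weeks = tuple(weeks) if weeks is not None else tuple(range(self.X.shape[1]))

    def fit(self, variance_threshold: float = 0.99) -> "FPCAResults":
        X = self.X
        n, J = X.shape
        obs = ~np.isnan(X)
        mu = np.nanmean(X, axis=0)
        Xc = np.where(obs, X - mu[None, :], 0.0)

        pair_n = obs.astype(float).T @ obs.astype(float)
        bad = np.argwhere(pair_n < 2)
        if len(bad):
            j, k = bad[0]
            raise ValueError(
                f"fewer than 2 pairwise-complete observations for week pair "
                f"({self.weeks[j]}, {self.weeks[k]})"
            )
        S = Xc.T @ Xc
        C = S / (pair_n - 1.0)

        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: entry of largest magnitude positive
        for k in range(J):
            j = int(np.argmax(np.abs(evecs[:, k])))
            if evecs[j, k] < 0:
                evecs[:, k] = -evecs[:, k]

        total = evals.sum()
        if total <= 0:
            raise ValueError("degenerate trajectories: all eigenvalues zero")
        n_comp = _select_k(evals, variance_threshold)

        C_psd = (evecs * evals[None, :]) @ evecs.T
        scores = np.zeros((n, J))
        # BLP score: lambda_k phi_k[o]' C[o,o]^+ x[o]
        pattern_cache: dict[tuple, np.ndarray] = {}
        for i in range(n):
            o = np.nonzero(obs[i])[0]
            key = tuple(o)
            if key not in pattern_cache:
                Coo_inv = np.linalg.pinv(C_psd[np.ix_(o, o)], rcond=1e-10)
                pattern_cache[key] = (evals[:, None] * evecs[o, :].T) @ Coo_inv
            scores[i] = pattern_cache[key] @ (X[i, o] - mu[o])

        return FPCAResults(
            mean=mu,
            eigenfunctions=evecs.T,
            eigenvalues=evals,
            n_components=n_comp,
            scores=scores,
            weeks=self.weeks,
            variance_threshold=variance_threshold,
        )


def _select_k(eigenvalues: np.ndarray, threshold: float) -> int:
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("all eigenvalues zero")
    ratio = np.cumsum(eigenvalues) / total
    if threshold >= 1.0:
        return int(np.count_nonzero(eigenvalues > 0))
    return int(np.searchsorted(ratio, threshold) + 1)


def select_components(model: "FPCAResults", threshold: float = 0.99) -> int:
    """Smallest k whose cumulative variance ratio reaches ``threshold``."""
    return _select_k(model.eigenvalues, threshold)


@dataclass
class FPCAResults:
    """Eigenfunctions/eigenvalues on the week grid and per-trajectory scores."""

    mean: np.ndarray
    eigenfunctions: np.ndarray  # components x weeks
    eigenvalues: np.ndarray  # descending, >= 0
    n_components: int
    scores: np.ndarray  # trajectories x components (all J kept)
    weeks: tuple
    variance_threshold: float = 0.99

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        k = n_components if n_components is not None else len(self.eigenvalues)
        return self.mean[None, :] + self.scores[:, :k] @ self.eigenfunctions[:k]

    def summary(self) -> str:
        ratio = self.explained_variance_ratio()
        lines = [
            "Trajectory functional PCA",
            "=" * 40,
            f"trajectories: {self.scores.shape[0]}   weeks: {self.weeks}",
            f"components at {self.variance_threshold:.0%} variance: {self.n_components}",
            "eigenvalues: " + "  ".join(f"{v:.4g}" for v in self.eigenvalues),
            "variance ratio: " + "  ".join(f"{v:.3f}" for v in ratio),
        ]
        for k in range(self.n_components):
            vals = "  ".join(f"{v:6.3f}" for v in self.eigenfunctions[k])
            lines.append(f"  fPC{k + 1}: {vals}")
        return "\n".join(lines)


def fit_fpca(traj: TrajectoryMatrix, variance_threshold: float = 0.99) -> dict:
    """Fit a per-OTU fPCA for every OTU of a trajectory matrix."""
    return {
        otu: TrajectoryFPCA(traj.trajectories(otu), weeks=traj.weeks).fit(
            variance_threshold
        )
        for otu in traj.otus
    }


def score_features(models: dict, traj: TrajectoryMatrix) -> pd.DataFrame:
    """Stack selected-component fPC scores into a mouse x (otu, fPC) matrix."""
    cols, blocks = [], []
    for otu in traj.otus:
        res = models[otu]
        for k in range(res.n_components):
            cols.append(f"{otu}|fPC{k + 1}")
            blocks.append(res.scores[:, k])
    return pd.DataFrame(np.column_stack(blocks), index=traj.mice, columns=cols)


@dataclass
class GenotypeLassoFit:
    genotype: str
    C_selected: float
    coefficients: pd.Series  # per (otu|fPC) feature
    predictive_otus: list[str]
    cv_score: float


@dataclass
class PredictiveReport:
    per_genotype: dict = field(default_factory=dict)
    group_mean_scores: pd.DataFrame | None = None
    shape_report: dict = field(default_factory=dict)

    @property
    def predictive_otus(self) -> dict:
        return {g: fit.predictive_otus for g, fit in self.per_genotype.items()}


def lasso_logistic_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    genotype: str,
    seed: int = 0,
    folds: int = 5,
    Cs=None,
    one_se_rule: bool = True,
) -> GenotypeLassoFit | None:
    """L1-penalized logistic regression of diagnosis on fPC scores.

    The penalty is chosen by stratified k-fold cross-validated deviance
    with the one-standard-error rule: among penalties whose mean CV
    deviance is within one standard error of the best, the strongest is
    taken (guards against spurious selections when the scores carry no
    signal).  Returns None with a warning when only one diagnosis class is
    present.
    """
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    y = (labels.loc[features.index] == "OSCC").astype(int)
    if y.nunique() < 2:
        warnings.warn(f"genotype {genotype}: single diagnosis class; skipped")
        return None
    n_minority = int(y.value_counts().min())
    if n_minority < 2:
        warnings.warn(
            f"genotype {genotype}: minority diagnosis class has < 2 mice; skipped"
        )
        return None
    k = max(2, min(folds, n_minority))
    if Cs is None:
        Cs = np.logspace(-3, 2, 20)
    Cs = np.asarray(Cs, dtype=float)
    clf = LogisticRegressionCV(
        Cs=Cs,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        cv=StratifiedKFold(n_splits=k, shuffle=True, random_state=seed),
        max_iter=2000,
        refit=False,
        random_state=seed,
    )
    X = features.to_numpy()
    clf.fit(X, y.to_numpy())
    scores = clf.scores_[1]  # folds x Cs, higher = better (neg log loss)
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
    best = int(np.argmax(mean))
    if one_se_rule:
        ok = np.nonzero(mean >= mean[best] - se[best])[0]
        sel = int(ok[np.argmin(Cs[ok])])
    else:
        sel = best
    final = LogisticRegression(
        penalty="l1", C=float(Cs[sel]), solver="liblinear", max_iter=2000,
        random_state=seed,
    )
    final.fit(X, y.to_numpy())
    coefs = pd.Series(final.coef_[0], index=features.columns)
    predictive = sorted({c.split("|")[0] for c in coefs.index[coefs != 0]})
    return GenotypeLassoFit(
        genotype=genotype,
        C_selected=float(Cs[sel]),
        coefficients=coefs,
        predictive_otus=predictive,
        cv_score=float(mean[sel]),
    )


# reference temporal shapes used to label score signs (see Results wording)
def _templates(weeks: tuple) -> dict[str, np.ndarray]:
    w = np.asarray(weeks, dtype=float)
    rise = np.tanh((w - 12.0) / 3.0)  # low -> high between weeks 8 and 16
    parab = (w - 12.0) ** 2  # decrease to week 12 then increase
    out = {}
    for name, v in (("fPC1", rise), ("fPC2", parab)):
        v = v - v.mean()
        out[name] = v / np.linalg.norm(v)
    return out


def shape_match_report(models: dict, weeks: tuple, min_cosine: float = 0.8) -> dict:
    """Check fitted eigenfunctions against the canonical trend templates.

    fPC1 template: monotone low-to-high transition between weeks 8 and 16;
    fPC2 template: parabolic dip with minimum near week 12.  Score-sign
    interpretation is only meaningful for OTUs whose eigenfunctions match.
    """
    templates = _templates(weeks)
    report = {}
    for otu, res in models.items():
        entry = {}
        for k, name in enumerate(("fPC1", "fPC2")):
            if k < res.eigenfunctions.shape[0]:
                cos = float(np.dot(res.eigenfunctions[k], templates[name]))
                entry[name] = {"cosine": cos, "matches": abs(cos) >= min_cosine}
        report[otu] = entry
    return report


def group_average_scores(
    models: dict, traj: TrajectoryMatrix
) -> pd.DataFrame:
    """Mean fPC score per (otu, component, genotype, diagnosis)."""
    meta = traj.mouse_meta
    rows = []
    for otu in traj.otus:
        res = models[otu]
        for k in range(res.n_components):
            s = pd.Series(res.scores[:, k], index=traj.mice)
            grouped = s.groupby([meta["genotype"], meta["diagnosis"]]).mean()
            for (geno, diag), m in grouped.items():
                rows.append((otu, f"fPC{k + 1}", geno, diag, float(m)))
    return pd.DataFrame(
        rows, columns=["otu", "component", "genotype", "diagnosis", "mean_score"]
    )


def predict_diagnosis(
    traj: TrajectoryMatrix,
    models: dict | None = None,
    seed: int = 0,
    folds: int = 5,
    variance_threshold: float = 0.99,
) -> PredictiveReport:
    """Full trend-prediction pass: fPCA -> per-genotype lasso logistic."""
    if models is None:
        models = fit_fpca(traj, variance_threshold)
    features = score_features(models, traj)
    meta = traj.mouse_meta
    report = PredictiveReport()
    for geno in sorted(meta["genotype"].unique()):
        idx = meta.index[meta["genotype"] == geno]
        fit = lasso_logistic_cv(
            features.loc[idx], meta["diagnosis"], geno, seed=seed, folds=folds
        )
        if fit is not None:
            report.per_genotype[geno] = fit
    report.group_mean_scores = group_average_scores(models, traj)
    report.shape_report = shape_match_report(models, traj.weeks)
    return report
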