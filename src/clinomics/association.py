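"""Clinical-genomic association via penalized regression, statsmodels-style.

:class:`ElasticNetAssociation` is the model object: it holds an integrated
feature x sample matrix and an encoded clinical outcome, aligned on their
common samples. ``fit()`` selects the penalty by 10-fold cross-validation
(or fits at a fixed penalty) and returns an :class:`AssociationResults`
carrying the coefficients, the CV curve, rank-proportional feature scores,
per-entity aggregated scores, and a ``summary()`` table. Bootstrap rank
aggregation — refitting on with-replacement resamples and averaging the
rank scores — hangs off the results object and quantifies how stably each
entity is selected.

Scoring rule: within one fit, the m features with nonzero coefficients are
ranked 1..m by decreasing |coefficient| (ties broken lexicographically by
feature tag) and the feature at rank r scores (m - r + 1)/m, a value in
(0, 1]. An entity's score is the sum of the scores of its selected features
across platforms, so a gene supported by several assays outranks one
supported by a single assay at equal per-feature strength. A positive
coefficient is reported as a direct association (the outcome increases with
the predictor), a negative one as inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical import OutcomeVector
from .matrices import IntegratedMatrix
from .solver import (
    BOOTSTRAP_LAMBDA_RATIO,
    ElasticNetFit,
    _as_design,
    cv_select_lambda,
    fit_elastic_net,
    lambda_grid,
    lambda_max,
)

SCORE_METHODS = ("linear", "inverse")


def _row_tags(index: pd.Index) -> pd.DataFrame:
    """(entity, platform, feature) per design row, for any index shape."""
    if isinstance(index, pd.MultiIndex) and index.nlevels == 3:
        return pd.DataFrame(
            {
                "entity": index.get_level_values("entity"),
                "platform": index.get_level_values("platform"),
                "feature": index.get_level_values("feature"),
            }
        )
    labels = [str(i) for i in index]
    return pd.DataFrame({"entity": labels, "platform": "NA", "feature": labels})


def score_features(fit: ElasticNetFit, method: str = "linear") -> pd.DataFrame:
    """Rank-proportional scores for the selected features of one fit.

    Returns a frame with columns entity/platform/feature/coef/rank/score/
    direction, one row per nonzero-coefficient feature; an all-zero fit gives
    an empty frame.
    """
    if method not in SCORE_METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    nz = fit.coef[fit.coef != 0]
    tags = _row_tags(nz.index)
    tags["coef"] = nz.to_numpy()
    if tags.empty:
        tags["rank"] = pd.Series(dtype=int)
        tags["score"] = pd.Series(dtype=float)
        tags["direction"] = pd.Series(dtype=int)
        return tags
    tags["abs"] = tags["coef"].abs()
    tags = tags.sort_values(
        ["abs", "entity", "platform", "feature"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    m = len(tags)
    ranks = np.arange(1, m + 1)
    tags["rank"] = ranks
    tags["score"] = (m - ranks + 1) / m if method == "linear" else 1.0 / ranks
    tags["direction"] = np.sign(tags["coef"]).astype(int)
    return tags.drop(columns="abs")


def aggregate_genes(scores: pd.DataFrame) -> pd.DataFrame:
    """Sum feature scores per entity; directions are kept per platform.

    Returns a frame indexed by entity with columns score / platforms /
    directions, sorted by score descending (entity id breaks ties).
    """
    if scores.empty:
        return pd.DataFrame(columns=["score", "platforms", "directions"])
    grouped = scores.groupby("entity", sort=False)
    out = grouped["score"].sum().to_frame("score")
    out["platforms"] = grouped.apply(
        lambda g: ",".join(sorted(set(g["platform"]))), include_groups=False
    )
    out["directions"] = grouped.apply(
        lambda g: ",".join(
            f"{p}:{'+' if d >= 0 else '-'}"
            for p, d in sorted(zip(g["platform"], g["direction"]))
        ),
        include_groups=False,
    )
    # deterministic order: score descending, entity id breaks ties
    out = (
        out.reset_index()
        .sort_values(["score", "entity"], ascending=[False, True], kind="stable")
        .set_index("entity")
    )
    return out


@dataclass
class GeneRanking:
    """Bootstrap-aggregated per-entity ranking.

    ``table`` is indexed by entity and carries the mean rank score over the B
    resamples (entities absent from a resample contribute 0), the selection
    frequency (fraction of resamples with a positive score), the score
    variance across resamples, supporting platforms with direction signs, and
    the final rank. ``features`` holds per-feature mean scores and direction
    signs. Ordering: mean score descending, ties broken by higher selection
    frequency then entity id.
    """

    table: pd.DataFrame
    features: pd.DataFrame
    B: int

    @property
    def entities(self) -> pd.Index:
        return self.table.index

    def candidates(self, min_frequency: float = 0.0) -> list[str]:
        """Entities with positive aggregate score (optionally also requiring a
        minimum bootstrap selection frequency)."""
        t = self.table
        keep = (t["score"] > 0) & (t["selection_frequency"] >= min_frequency)
        return [str(e) for e in t.index[keep]]

    def top(self, n: int) -> list[str]:
        return [str(e) for e in self.table.index[:n]]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        cols = [
            "entity",
            "score",
            "selection_frequency",
            "score_variance",
            "platforms",
            "directions",
            "rank",
        ]
        return out[cols]


def bootstrap_rank(
    X,
    y,
    alpha: float = 0.5,
    B: int = 100,
    seed: int = 0,
    k: int = 10,
    grid: np.ndarray | None = None,
    score_method: str = "linear",
) -> GeneRanking:
    """Bootstrap rank aggregation: resample samples with replacement B times,
    re-run CV-penalized elastic net on each resample, score and aggregate.

    One RNG stream (from ``seed``) drives both the resampling and the CV fold
    seeds, so the whole procedure is reproducible from (data, alpha, B, seed).
    Labelled inputs are first put into canonical order (samples sorted by id,
    features by tag), making the ranking invariant to the order the data
    arrived in.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, y = _canonical_order(X, y)
    Xa, tags = _as_design(X)
    ya = _as_response_array(y)
    n = Xa.shape[0]
    row_tags = _row_tags(tags)
    entities = pd.Index(pd.unique(row_tags["entity"]), name="entity")

    rng = np.random.default_rng(seed)
    score_sum = pd.Series(0.0, index=entities)
    score_sumsq = pd.Series(0.0, index=entities)
    hit_count = pd.Series(0, index=entities, dtype=int)
    feat_key = pd.MultiIndex.from_frame(row_tags[["entity", "platform", "feature"]])
    feat_score_sum = pd.Series(0.0, index=feat_key)
    feat_coef_sum = pd.Series(0.0, index=feat_key)

    for _ in range(B):
        idx = rng.integers(0, n, n)
        fold_seed = int(rng.integers(0, 2**31))
        Xb = np.asfortranarray(Xa[idx])
        yb = ya[idx]
        bgrid = grid
        if bgrid is None:
            # with-replacement resamples hold ~63% distinct samples; use the
            # shorter path conventional for the under-determined regime
            bgrid = lambda_grid(
                lambda_max(Xb, yb, alpha), ratio=BOOTSTRAP_LAMBDA_RATIO
            )
        Xb_df = pd.DataFrame(Xb.T, index=tags)
        _, fit, _ = cv_select_lambda(Xb_df, yb, alpha=alpha, k=k, grid=bgrid, seed=fold_seed)
        scores = score_features(fit, method=score_method)
        agg = aggregate_genes(scores)
        if not agg.empty:
            s = agg["score"].reindex(entities).fillna(0.0)
        else:
            s = pd.Series(0.0, index=entities)
        score_sum += s
        score_sumsq += s**2
        hit_count += (s > 0).astype(int)
        if not scores.empty:
            skey = pd.MultiIndex.from_frame(scores[["entity", "platform", "feature"]])
            feat_score_sum = feat_score_sum.add(
                pd.Series(scores["score"].to_numpy(), index=skey), fill_value=0.0
            )
            feat_coef_sum = feat_coef_sum.add(
                pd.Series(scores["coef"].to_numpy(), index=skey), fill_value=0.0
            )

    mean = score_sum / B
    if B > 1:
        var = (score_sumsq - B * mean**2) / (B - 1)
        var = var.clip(lower=0.0)
    else:
        var = pd.Series(0.0, index=entities)
    freq = hit_count / B

    feats = pd.DataFrame(
        {
            "mean_score": feat_score_sum / B,
            "direction": np.sign(feat_coef_sum).astype(int),
        }
    )
    feats.index.names = ["entity", "platform", "feature"]
    feats = feats[feats["mean_score"] > 0].reset_index()

    directions = {
        e: ",".join(
            f"{p}:{'+' if d >= 0 else '-'}"
            for p, d in sorted(
                zip(g["platform"], g["direction"]),
            )
        )
        for e, g in feats.groupby("entity")
    }
    platforms = {
        e: ",".join(sorted(set(g["platform"]))) for e, g in feats.groupby("entity")
    }
    table = pd.DataFrame(
        {
            "score": mean,
            "selection_frequency": freq,
            "score_variance": var,
            "platforms": pd.Series(platforms).reindex(entities).fillna(""),
            "directions": pd.Series(directions).reindex(entities).fillna(""),
        }
    )
    table = (
        table.reset_index()
        .sort_values(
            ["score", "selection_frequency", "entity"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("entity")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return GeneRanking(table=table, features=feats, B=B)


def _canonical_order(X, y):
    """Sort samples by id and features by tag when the inputs carry labels."""
    if isinstance(X, IntegratedMatrix):
        frame = X.values
    elif isinstance(X, pd.DataFrame):
        frame = X
    else:
        return X, y  # bare arrays: caller owns the ordering
    original_columns = list(frame.columns)
    frame = frame.sort_index(axis=0).sort_index(axis=1)
    if isinstance(y, OutcomeVector):
        ys = y.values
    elif isinstance(y, pd.Series):
        ys = y
    else:
        ys = pd.Series(np.asarray(y, dtype=float), index=original_columns)
    return frame, ys.loc[frame.columns]


def _as_response_array(y) -> np.ndarray:
    if isinstance(y, OutcomeVector):
        return y.values.to_numpy(dtype=float)
    if isinstance(y, pd.Series):
        return y.to_numpy(dtype=float)
    return np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class ElasticNetAssociation:
    """Model: elastic-net regression of a clinical outcome on an integrated
    molecular feature space.

    Parameters
    ----------
    X
        :class:`IntegratedMatrix` (features x samples) — or a DataFrame with
        the same orientation for low-level use.
    y
        :class:`OutcomeVector` (or Series indexed by sample id). Samples are
        aligned on the intersection, in X's column order; samples lacking
        either data or outcome are dropped.
    alpha
        Elastic-net mixing weight in (0, 1]; 0.5 by default (an even L1/L2
        mix; configurable because association sparsity is a modelling choice).
    """

    def __init__(self, X, y, alpha: float = 0.5):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        self.alpha = float(alpha)
        if isinstance(X, IntegratedMatrix):
            data = X.values
        else:
            data = pd.DataFrame(X)
        yv = y.values if isinstance(y, OutcomeVector) else pd.Series(y)
        common = [s for s in data.columns if s in set(yv.index)]
        if len(common) < 2:
            raise ValueError("fewer than 2 samples shared between X and y")
        self.X = data[common]
        self.y = yv.loc[common].astype(float)
        self.outcome = y if isinstance(y, OutcomeVector) else None
        self.samples = pd.Index(common)

    @property
    def nobs(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.X)

    def fit(
        self,
        lam: float | None = None,
        cv: int = 10,
        grid: np.ndarray | None = None,
        seed: int = 0,
    ) -> "AssociationResults":
        """Fit the model; with ``lam=None`` the penalty is selected by
        ``cv``-fold cross-validation minimizing mean held-out squared error."""
        if lam is not None:
            fit = fit_elastic_net(self.X, self.y, alpha=self.alpha, lam=lam)
        else:
            _, fit, _ = cv_select_lambda(
                self.X, self.y, alpha=self.alpha, k=cv, grid=grid, seed=seed
            )
        return AssociationResults(self, fit)


class AssociationResults:
    """Results of one elastic-net association fit."""

    def __init__(self, model: ElasticNetAssociation, fit: ElasticNetFit):
        self.model = model
        self.fit = fit
        self.params = fit.coef
        self.intercept = fit.intercept
        self.lambda_ = fit.lam
        self.alpha = fit.alpha
        self.cv_curve = fit.cv_curve

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_selected(self) -> int:
        return int((self.params != 0).sum())

    def predict(self) -> pd.Series:
        pred = self.fit.predict(self.model.X.to_numpy().T)
        return pd.Series(pred, index=self.model.samples)

    @property
    def resid(self) -> pd.Series:
        return self.model.y - self.predict()

    @property
    def mse(self) -> float:
        return float((self.resid**2).mean())

    def score_table(self, method: str = "linear") -> pd.DataFrame:
        return score_features(self.fit, method=method)

    def gene_scores(self, method: str = "linear") -> pd.DataFrame:
        return aggregate_genes(self.score_table(method=method))

    def bootstrap(
        self,
        B: int = 100,
        seed: int = 0,
        k: int = 10,
        grid: np.ndarray | None = None,
        score_method: str = "linear",
    ) -> GeneRanking:
        """Bootstrap rank aggregation on this model's aligned data."""
        return bootstrap_rank(
            self.model.X,
            self.model.y,
            alpha=self.model.alpha,
            B=B,
            seed=seed,
            k=k,
            grid=grid,
            score_method=score_method,
        )

    def test_candidates(self, matrices, ranking=None, threshold: float = 0.01, rule=None):
        """Per-candidate post-hoc tests (Fisher / Mann-Whitney with Bonferroni
        correction) against the dichotomized outcome; see
        :func:`clinomics.posthoc.test_candidates`."""
        from .posthoc import test_candidates as _tc

        if self.model.outcome is None:
            raise ValueError("post-hoc testing requires an OutcomeVector")
        if ranking is None:
            agg = self.gene_scores()
            ranking = _ranking_from_scores(agg)
        return _tc(ranking, matrices, self.model.outcome, threshold=threshold, rule=rule)

    def summary(self, top: int = 10) -> str:
        """Readable fit summary: penalty, sparsity, and leading entities."""
        agg = self.gene_scores()
        lines = [
            "Elastic-net clinical-genomic association",
            "=" * 44,
            f"observations:        {self.nobs}",
            f"features:            {self.model.n_features}",
            f"alpha (L1 mix):      {self.alpha:.3f}",
            f"lambda:              {self.lambda_:.6g}"
            + ("  (10-fold CV)" if self.cv_curve is not None else ""),
            f"selected features:   {self.df_selected}",
            f"intercept:           {self.intercept:.6g}",
            f"training MSE:        {self.mse:.6g}",
            "",
            f"top entities (of {len(agg)} scored)",
            "-" * 44,
        ]
        for entity, row in agg.head(top).iterrows():
            lines.append(
                f"{str(entity):<20s} score={row['score']:=7.3f}  "
                f"[{row['directions']}]"
            )
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """Held-out MSE against the penalty grid (requires a CV fit)."""
        if self.cv_curve is None:
            raise ValueError("no CV curve: model was fitted at a fixed penalty")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.cv_curve["lam"], self.cv_curve["mse"], marker=".")
        ax.axvline(self.lambda_, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("penalty $\\lambda$")
        ax.set_ylabel("mean held-out squared error")
        return ax


def _ranking_from_scores(agg: pd.DataFrame) -> GeneRanking:
    """Wrap a single fit's aggregated scores as a degenerate (B=1) ranking."""
    table = agg.copy()
    if table.empty:
        table = pd.DataFrame(
            columns=["score", "selection_frequency", "score_variance", "platforms", "directions", "rank"]
        )
        table.index.name = "entity"
        return GeneRanking(table=table, features=pd.DataFrame(
            columns=["entity", "platform", "feature", "mean_score", "direction"]
        ), B=1)
    table["selection_frequency"] = 1.0
    table["score_variance"] = 0.0
    table["rank"] = np.arange(1, len(table) + 1)
    feats = pd.DataFrame(columns=["entity", "platform", "feature", "mean_score", "direction"])
    return GeneRanking(table=table, features=feats, B=1)
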