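"""Random-forest prediction of the Crossover-Potential landscape from
genomic and epigenomic feature tracks.

The target CO_P map and the feature tracks share a 300-kb / 50-kb sliding
windowing.  Features are correlated with the target (Spearman), ranked by
permutation importance from a full-panel random-forest fit, screened with a
stepwise cumulative variance-explained curve (out-of-bag R^2), and the
predictive value of the panel is assessed by leave-one-chromosome-out
cross-validation: the forest never sees the held-out chromosome's windows.
Forest hyperparameters default to ntree=2000, mtry=3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from copmap.layout import GenomeLayout
from copmap.tracks import WindowedTrack, window_starts

CANONICAL_FEATURES = [
    "SNPs", "INV_TRANS", "Synteny", "Genes", "TEs", "GC", "ATAC", "DNase",
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9me2", "H3K27me1",
    "mCG", "mCHG", "mCHH", "MNase",
]


@dataclass
class FeaturePanel:
    """Named feature tracks sharing one windowing."""

    tracks: dict[str, WindowedTrack]

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("empty feature panel")
        ref = next(iter(self.tracks.values()))
        for name, t in self.tracks.items():
            if not t.same_windowing(ref):
                raise ValueError(f"feature {name!r} has mismatched windowing")
        # canonical (sorted) feature order: forest fits and importance
        # rankings become invariant to the order tracks were supplied in
        self.tracks = {name: self.tracks[name] for name in sorted(self.tracks)}

    @property
    def names(self) -> list[str]:
        return list(self.tracks)

    @property
    def reference(self) -> WindowedTrack:
        return next(iter(self.tracks.values()))

    def matrix(self, chroms: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix (windows x features) and the chromosome label per row."""
        ref = self.reference
        chroms = chroms if chroms is not None else list(ref.starts)
        cols = [
            np.concatenate([self.tracks[name].values[c] for c in chroms])
            for name in self.tracks
        ]
        labels = np.concatenate(
            [np.repeat(c, len(ref.starts[c])) for c in chroms]
        )
        return np.column_stack(cols), labels


@dataclass
class ModelReport:
    """Cross-validation and importance summary of one CO_P model."""

    feature_correlations: pd.DataFrame
    importance: pd.DataFrame                  # feature, importance, rank
    stepwise: pd.DataFrame                    # k, feature_added, oob_r2
    fold_r: dict[str, float]
    pooled_r: float
    predictions: dict[str, WindowedTrack]
    hyperparams: dict = field(default_factory=dict)


def _target_vector(target: WindowedTrack, panel: FeaturePanel,
                   chroms: list[str]) -> np.ndarray:
    if not target.same_windowing(panel.reference):
        raise ValueError("target and features have mismatched windowing")
    return np.concatenate([target.values[c] for c in chroms])


def _forest(ntree: int, mtry: int, seed: int, oob: bool = False) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        oob_score=oob,
        random_state=seed,
        min_samples_leaf=5,
        n_jobs=1,
    )


def correlate_features(target: WindowedTrack, panel: FeaturePanel) -> pd.DataFrame:
    """Spearman correlation of each feature with the target, sign preserved;
    windows with a missing value in either member are dropped pairwise."""
    chroms = list(panel.reference.starts)
    y = _target_vector(target, panel, chroms)
    rows = []
    for name in panel.names:
        x = np.concatenate([panel.tracks[name].values[c] for c in chroms])
        ok = np.isfinite(x) & np.isfinite(y)
        r = stats.spearmanr(x[ok], y[ok]).statistic
        rows.append({"feature": name, "spearman_r": float(r)})
    return pd.DataFrame(rows)


def rank_importance(target: WindowedTrack, panel: FeaturePanel,
                    chroms: list[str] | None = None,
                    ntree: int = 2000, mtry: int = 3, seed: int = 0,
                    n_repeats: int = 5) -> pd.DataFrame:
    """Permutation importance of every feature from a full-panel fit."""
    X, labels = panel.matrix(chroms)
    use = chroms if chroms is not None else list(panel.reference.starts)
    y = _target_vector(target, panel, use)
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    model = _forest(ntree, mtry, seed).fit(X[ok], y[ok])
    imp = permutation_importance(
        model, X[ok], y[ok], n_repeats=n_repeats, random_state=seed
    )
    df = pd.DataFrame(
        {"feature": panel.names, "importance": imp.importances_mean}
    ).sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def stepwise_importance(target: WindowedTrack, panel: FeaturePanel,
                        ntree: int = 2000, mtry: int = 3, seed: int = 0,
                        importance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cumulative variance-explained curve over top-k feature sets.

    Features enter in permutation-importance order; for each k the forest is
    refit on the top-k features and the out-of-bag R^2 recorded.  The curve
    is reported as measured, not forced monotone.
    """
    if importance is None:
        importance = rank_importance(target, panel, ntree=ntree, mtry=mtry, seed=seed)
    order = list(importance["feature"])
    chroms = list(panel.reference.starts)
    y = _target_vector(target, panel, chroms)
    if np.nanstd(y) == 0:
        raise ValueError("degenerate target: constant values")
    X, _ = panel.matrix()
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    name_idx = {n: i for i, n in enumerate(panel.names)}
    rows = []
    for k in range(1, len(order) + 1):
        cols = [name_idx[n] for n in order[:k]]
        model = _forest(ntree, min(mtry, k), seed, oob=True).fit(X[ok][:, cols], y[ok])
        rows.append({"k": k, "feature_added": order[k - 1], "oob_r2": float(model.oob_score_)})
    return pd.DataFrame(rows)


def fit_predict_cv(target: WindowedTrack, panel: FeaturePanel,
                   layout: GenomeLayout | None = None,
                   exclude: set[str] | None = None,
                   ntree: int = 2000, mtry: int = 3, seed: int = 0,
                   stepwise: bool = False) -> ModelReport:
    """Leave-one-chromosome-out cross-validated CO_P prediction.

    Each fold trains on all non-excluded chromosomes but one and predicts
    the held-out chromosome's windows; per-fold and pooled predicted-vs-
    observed Spearman correlations are reported.  ``exclude`` defaults to
    the layout's excluded-for-interference set (rearranged chromosomes).
    """
    if exclude is None:
        exclude = set(layout.excluded_for_interference) if layout is not None else set()
    chroms = [c for c in panel.reference.starts if c not in exclude]
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes after exclusions")
    y_all = _target_vector(target, panel, list(panel.reference.starts))
    if np.nanstd(y_all) == 0:
        raise ValueError("degenerate target: constant values")

    fold_r: dict[str, float] = {}
    predictions: dict[str, WindowedTrack] = {}
    pooled_obs: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for held_out in chroms:
        train = [c for c in chroms if c != held_out]
        X_tr, _ = panel.matrix(train)
        y_tr = _target_vector(target, panel, train)
        ok_tr = np.all(np.isfinite(X_tr), axis=1) & np.isfinite(y_tr)
        model = _forest(ntree, mtry, seed).fit(X_tr[ok_tr], y_tr[ok_tr])
        X_te, _ = panel.matrix([held_out])
        y_te = _target_vector(target, panel, [held_out])
        ok_te = np.all(np.isfinite(X_te), axis=1)
        pred = np.full(len(y_te), np.nan)
        pred[ok_te] = model.predict(X_te[ok_te])
        ref = panel.reference
        predictions[held_out] = WindowedTrack(
            ref.window_size, ref.step,
            {held_out: ref.starts[held_out].copy()}, {held_out: pred},
            target.normalization,
        )
        both = ok_te & np.isfinite(y_te)
        fold_r[held_out] = float(stats.spearmanr(y_te[both], pred[both]).statistic)
        pooled_obs.append(y_te[both])
        pooled_pred.append(pred[both])
    pooled_r = float(
        stats.spearmanr(np.concatenate(pooled_obs), np.concatenate(pooled_pred)).statistic
    )
    correlations = correlate_features(target, panel)
    importance = rank_importance(target, panel, chroms=chroms,
                                 ntree=ntree, mtry=mtry, seed=seed)
    steps = (
        stepwise_importance(target, panel, ntree=ntree, mtry=mtry, seed=seed,
                            importance=importance)
        if stepwise
        else pd.DataFrame(columns=["k", "feature_added", "oob_r2"])
    )
    return ModelReport(
        feature_correlations=correlations,
        importance=importance,
        stepwise=steps,
        fold_r=fold_r,
        pooled_r=pooled_r,
        predictions=predictions,
        hyperparams={"ntree": ntree, "mtry": mtry, "seed": seed},
    )


def synthetic_panel(layout: GenomeLayout, rng: np.random.Generator,
                    window: int = 300_000, step: int = 50_000,
                    names: list[str] | None = None,
                    smooth: int = 20) -> FeaturePanel:
    """Smooth random feature tracks (for tests and parameter-recovery runs).

    Each track is a moving average of white noise, giving the megabase-scale
    autocorrelation real chromatin tracks show.
    """
    names = names if names is not None else list(CANONICAL_FEATURES)
    tracks = {}
    for name in names:
        starts = {}
        values = {}
        for chrom, length in layout.chromosomes:
            s = window_starts(length, window, step)
            raw = rng.normal(size=len(s) + smooth)
            kernel = np.ones(smooth) / smooth
            values[chrom] = np.convolve(raw, kernel, mode="valid")[: len(s)]
            starts[chrom] = s
        tracks[name] = WindowedTrack(window, step, starts, values, "raw_count")
    return FeaturePanel(tracks)


def synthetic_target(panel: FeaturePanel, drivers: list[str],
                     rng: np.random.Generator, noise_sd: float = 0.05) -> WindowedTrack:
    """A CO_P-like target built as a known nonlinear function of a few
    driver features plus Gaussian noise (parameter-recovery ground truth)."""
    ref = panel.reference
    values = {}
    for chrom in ref.starts:
        parts = [panel.tracks[d].values[chrom] for d in drivers]
        y = np.zeros(len(ref.starts[chrom]))
        for i, x in enumerate(parts):
            y = y + (i + 1) * x
        y = y + 0.5 * parts[0] * parts[min(1, len(parts) - 1)] + np.tanh(parts[-1])
        values[chrom] = y + rng.normal(scale=noise_sd, size=len(y))
    return WindowedTrack(ref.window_size, ref.step,
                         {c: s.copy() for c, s in ref.starts.items()},
                         values, "raw_count")
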