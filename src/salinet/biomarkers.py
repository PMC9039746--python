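"""Order-level biomarker discovery for salinity.

Aggregates OTU abundances to a taxonomic rank, regresses salinity on the
resulting relative-abundance features with a bagged regression forest,
and prunes features by repeated cross-validated recursive elimination
(halving the feature count each step, ranked by impurity importance).
The selected marker set is the subset size minimising mean CV error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .datatypes import OtuTable, SalinetError, TaxonomyTable


def aggregate_to_rank(
    table: OtuTable, taxonomy: TaxonomyTable, rank: str = "order"
) -> pd.DataFrame:
    """Per-sample relative abundances summed within each taxon at ``rank``.

    OTUs whose label at the rank is "unclassified" (or missing) are
    dropped, with a warning reporting how many; rows therefore sum to
    at most 1.
    """
    taxonomy.require_covers(table.otu_ids)
    labels = taxonomy.rank(rank).loc[table.otu_ids]
    unassigned = labels.isna() | (labels == "unclassified")
    if unassigned.all():
        raise SalinetError(f"no OTUs classified at rank {rank!r}")
    if unassigned.any():
        warnings.warn(
            f"dropping {int(unassigned.sum())} OTUs unclassified at rank {rank!r}", UserWarning
        )
    rel = table.relative_abundance()
    kept = rel.loc[:, ~unassigned.to_numpy()]
    return kept.T.groupby(labels[~unassigned]).sum().T


def _halving_schedule(n_features: int) -> list[int]:
    sizes = [n_features]
    while sizes[-1] > 1:
        sizes.append(max(1, int(np.ceil(sizes[-1] / 2))))
        if sizes[-1] == sizes[-2]:
            sizes[-1] = sizes[-2] - 1
    return sizes


@dataclass
class RfResult:
    importances: pd.Series  # full-model impurity importances
    cv_errors: pd.DataFrame  # size, mean_mse, sd
    selected_markers: list[str]
    selected_size: int
    accuracy_pct: float  # 100 * (1 - MSE_oob / var(salinity))
    wilcoxon_p: float
    oof_predictions: pd.Series


def rfcv_biomarkers(
    features: pd.DataFrame,
    salinity: pd.Series,
    ntree: int = 1000,
    folds: int = 10,
    repeats: int = 5,
    seed: int | None = 0,
) -> RfResult:
    """Cross-validated recursive feature elimination with a regression forest.

    Within each fold a forest is fit on the training samples, the test
    error recorded, the features re-ranked by impurity importance and
    halved, repeating down the schedule; the CV error per subset size is
    averaged over folds and repeats.  The reported predictive accuracy
    is the out-of-bag variance explained, ``100 * (1 - MSE_oob /
    var(y))``, of a final forest refit on the selected features, and the
    Wilcoxon signed-rank test compares actual salinities with the
    out-of-fold predictions of that feature set.
    """
    y = salinity.loc[features.index].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise SalinetError("salinity is constant; nothing to regress")
    n, p = features.shape
    if n < folds:
        raise SalinetError(f"need at least {folds} samples for {folds}-fold CV")
    x_all = features.to_numpy(dtype=float)
    names = np.array(features.columns)
    sizes = _halving_schedule(p)
    rng = np.random.default_rng(seed)

    def make_forest(rs: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=ntree, random_state=rs, n_jobs=1, oob_score=True, bootstrap=True
        )

    errors = np.zeros((repeats, len(sizes)))
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        fold_err = np.zeros((folds, len(sizes)))
        for fi, (train, test) in enumerate(kf.split(x_all)):
            current = np.arange(p)
            for si, size in enumerate(sizes):
                if len(current) > size:
                    current = current[:size]  # already importance-ordered
                model = RandomForestRegressor(
                    n_estimators=ntree,
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1,
                )
                model.fit(x_all[np.ix_(train, current)], y[train])
                pred = model.predict(x_all[np.ix_(test, current)])
                fold_err[fi, si] = np.mean((y[test] - pred) ** 2)
                order = np.argsort(model.feature_importances_)[::-1]
                current = current[order]
        errors[rep] = fold_err.mean(axis=0)
    mean_err = errors.mean(axis=0)
    sd_err = errors.std(axis=0, ddof=1) if repeats > 1 else np.zeros_like(mean_err)
    best_idx = int(np.argmin(mean_err))
    selected_size = sizes[best_idx]

    # final ranking on all data, recursively halved to the selected size
    current = np.arange(p)
    full_model = make_forest(int(rng.integers(2**31)))
    full_model.fit(x_all, y)
    importances = pd.Series(full_model.feature_importances_, index=features.columns)
    ranked = current[np.argsort(full_model.feature_importances_)[::-1]]
    while len(ranked) > selected_size:
        nxt = max(selected_size, int(np.ceil(len(ranked) / 2)))
        ranked = ranked[:nxt]
        m = make_forest(int(rng.integers(2**31)))
        m.fit(x_all[:, ranked], y)
        ranked = ranked[np.argsort(m.feature_importances_)[::-1]]
    selected = ranked[:selected_size]

    final = make_forest(int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warning on tiny n
        final.fit(x_all[:, selected], y)
    mse_oob = float(np.mean((y - final.oob_prediction_) ** 2))
    accuracy = 100.0 * (1.0 - mse_oob / np.var(y))

    # out-of-fold predictions with the selected feature set
    oof = np.full(n, np.nan)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    for train, test in kf.split(x_all):
        m = RandomForestRegressor(
            n_estimators=ntree, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        m.fit(x_all[np.ix_(train, selected)], y[train])
        oof[test] = m.predict(x_all[np.ix_(test, selected)])
    diffs = y - oof
    if np.allclose(diffs, 0):
        wilcoxon_p = 1.0
    else:
        _, wilcoxon_p = stats.wilcoxon(y, oof)

    return RfResult(
        importances=importances.sort_values(ascending=False),
        cv_errors=pd.DataFrame({"size": sizes, "mean_mse": mean_err, "sd": sd_err}),
        selected_markers=[str(names[i]) for i in selected],
        selected_size=selected_size,
        accuracy_pct=float(accuracy),
        wilcoxon_p=float(wilcoxon_p),
        oof_predictions=pd.Series(oof, index=features.index, name="predicted_salinity"),
    )
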