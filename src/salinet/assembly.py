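"""Phylogenetic and taxonomic null models of community assembly.

Quantifies, for every pair of samples, whether their phylogenetic and
compositional turnover departs from chance, and translates the two
z-scores into a five-way assembly-process classification:

* βMNTD — abundance-weighted mean distance from each taxon in one
  community to its nearest relative in the other.
* βNTI — z-score of observed βMNTD against a null that shuffles taxon
  identities across the tips of the phylogeny; |βNTI| > 2 marks
  deterministic selection (βNTI > 2 variable/heterogeneous selection,
  βNTI < -2 homogeneous selection).
* RC_Bray — Bray-Curtis-based Raup-Crick index in [-1, 1], comparing the
  observed dissimilarity against communities assembled probabilistically
  from the metacommunity (occurrence frequency governs which taxa enter,
  relative abundance governs how individuals fill each community).
  Among the |βNTI| <= 2 pairs, RC_Bray < -0.95 marks homogenizing
  dispersal, RC_Bray > 0.95 dispersal limitation, and the middle band
  "undominated" assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import OtuTable, Phylogeny, SalinetError

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)

#: "Heterogeneous selection" is the alternative name in common use for
#: divergence under selection; the canonical label here is
#: "variable_selection".
PROCESS_ALIASES = {"heterogeneous_selection": "variable_selection"}

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def _aligned_arrays(table: OtuTable, tree: Phylogeny):
    """Counts restricted to OTUs with nonzero totals, plus patristic D."""
    totals = table.counts.sum(axis=0)
    present = totals.index[totals > 0].tolist()
    tree.require_tips(present)
    counts = table.counts[present].to_numpy(dtype=float)
    dist = tree.patristic_distances().loc[present, present].to_numpy(dtype=float)
    return counts, dist, present


def _beta_mntd_from(counts: np.ndarray, dist: np.ndarray, weighted: bool) -> np.ndarray:
    """βMNTD matrix for all sample pairs given a tip distance matrix.

    For each sample m, precompute per-OTU nearest-taxon distances into
    m's members; βMNTD(k, m) is then the average of two weighted dot
    products, which keeps the whole computation vectorised.
    """
    n_samples, n_otus = counts.shape
    if weighted:
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise SalinetError("all-zero sample in βMNTD")
        f = counts / totals
    else:
        pres = counts > 0
        f = pres / pres.sum(axis=1, keepdims=True)
    # min_into[m, i] = distance from OTU i to its nearest taxon in sample m
    min_into = np.empty((n_samples, n_otus))
    for m in range(n_samples):
        members = counts[m] > 0
        if not members.any():
            raise SalinetError("empty sample in βMNTD")
        d_to_m = dist[:, members].min(axis=1)
        # a taxon also present in m has nearest-relative distance to the
        # *other* community, itself included -> 0, which dist gives already
        min_into[m] = d_to_m
    bmntd = 0.5 * (f @ min_into.T + (f @ min_into.T).T)
    np.fill_diagonal(bmntd, 0.0)
    return bmntd


def beta_mntd(
    table: OtuTable, tree: Phylogeny, abundance_weighted: bool = True
) -> pd.DataFrame:
    """Observed β-mean nearest taxon distance between all sample pairs.

    βMNTD(k, m) = 1/2 [ Σ_i f_ik min_{j∈m} d_ij + Σ_j f_jm min_{i∈k} d_ij ]
    with f the relative abundances (presence weights if unweighted) and
    d the patristic distance.  Symmetric, nonnegative, zero on identical
    one-OTU overlaps of communities with themselves.
    """
    counts, dist, _ = _aligned_arrays(table, tree)
    mat = _beta_mntd_from(counts, dist, abundance_weighted)
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class BetaNtiResult:
    observed: pd.DataFrame  # βMNTD
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    bnti: pd.DataFrame  # NaN where the null SD is 0

    def pairs(self) -> pd.DataFrame:
        ids = list(self.bnti.index)
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    {
                        "sample_i": ids[i],
                        "sample_j": ids[j],
                        "bmntd": self.observed.iat[i, j],
                        "bnti": self.bnti.iat[i, j],
                    }
                )
        return pd.DataFrame(rows)


def beta_nti(
    table: OtuTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int | None = 0,
    abundance_weighted: bool = True,
) -> BetaNtiResult:
    """β-nearest taxon index for every sample pair.

    The null shuffles taxon identities uniformly among the tips present
    in the pooled table (equivalently, permutes rows/columns of the
    patristic distance matrix) and recomputes βMNTD each repetition.
    Pairs whose null SD is zero (e.g. a star phylogeny, where shuffling
    changes nothing) get NaN and are excluded from process fractions.
    """
    if n_null < 99:
        raise SalinetError("n_null must be at least 99")
    counts, dist, _ = _aligned_arrays(table, tree)
    obs = _beta_mntd_from(counts, dist, abundance_weighted)
    rng = np.random.default_rng(seed)
    n_tips = dist.shape[0]
    run_sum = np.zeros_like(obs)
    run_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        null = _beta_mntd_from(counts, dist[np.ix_(perm, perm)], abundance_weighted)
        run_sum += null
        run_sq += null**2
    mean = run_sum / n_null
    var = run_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None)) * np.sqrt(n_null / max(n_null - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / np.where(sd > 1e-12, sd, 1.0), np.nan)
    np.fill_diagonal(z, 0.0)
    ids = table.sample_ids
    wrap = lambda m: pd.DataFrame(m, index=ids, columns=ids)
    return BetaNtiResult(
        observed=wrap(obs), null_mean=wrap(mean), null_sd=wrap(sd), bnti=wrap(z)
    )


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occ_freq: np.ndarray,
    rel_abund: np.ndarray,
) -> np.ndarray:
    """One Raup-Crick null community with fixed richness and total count.

    Taxa enter with probability proportional to metacommunity occurrence
    frequency (without replacement); each receives one individual, and
    the remaining ``total - richness`` individuals are assigned
    multinomially in proportion to metacommunity relative abundance.
    """
    n = len(occ_freq)
    chosen = rng.choice(n, size=richness, replace=False, p=occ_freq / occ_freq.sum())
    community = np.zeros(n)
    community[chosen] = 1
    if total > richness:
        w = rel_abund[chosen]
        extra = rng.multinomial(total - richness, w / w.sum())
        community[chosen] += extra
    return community


def rc_bray(
    table: OtuTable,
    n_null: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick index for every sample pair.

    RC = 2 * [ (#{null BC < obs BC} + 0.5 * #{null BC = obs BC}) / n ] - 1,
    in [-1, 1]; -1 means far more similar than the stochastic null,
    +1 far less similar.  Null draws are generated per sample (each
    repetition pairs the r-th null community of each sample), preserving
    observed richness and total counts.
    """
    if n_null < 99:
        raise SalinetError("n_null must be at least 99")
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise SalinetError(f"samples with zero total count: {bad}")
    occ_freq = (counts > 0).mean(axis=0)
    rel_abund = counts.sum(axis=0) / counts.sum()
    richness = (counts > 0).sum(axis=1)
    n_samples = counts.shape[0]
    rng = np.random.default_rng(seed)

    obs_bc = squareform(pdist(counts, metric="braycurtis"))
    below = np.zeros((n_samples, n_samples))
    equal = np.zeros((n_samples, n_samples))
    for _ in range(n_null):
        nulls = np.stack(
            [
                _null_community(rng, int(richness[k]), int(totals[k]), occ_freq, rel_abund)
                for k in range(n_samples)
            ]
        )
        null_bc = squareform(pdist(nulls, metric="braycurtis"))
        below += null_bc < obs_bc - 1e-12
        equal += np.abs(null_bc - obs_bc) <= 1e-12
    rc = 2.0 * ((below + 0.5 * equal) / n_null) - 1.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


def classify_assembly(bnti: float, rc: float) -> str:
    """Five-way process label from the two null-model z-scores.

    βNTI > 2: variable selection; βNTI < -2: homogeneous selection;
    otherwise RC_Bray < -0.95: homogenizing dispersal, > 0.95: dispersal
    limitation, else undominated.  Boundary values (|βNTI| = 2,
    |RC| = 0.95) fall to the stochastic / undominated side, matching the
    strict inequalities of the published thresholds.
    """
    if np.isnan(bnti):
        return "undefined"
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if np.isnan(rc):
        return "undefined"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    return "undominated"


def assembly_pairs(
    table: OtuTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int | None = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Per-pair βMNTD, βNTI, Bray-Curtis, RC_Bray and process label."""
    rng = np.random.default_rng(seed)
    nti = beta_nti(
        table, tree, n_null=n_null, seed=int(rng.integers(2**31)),
        abundance_weighted=abundance_weighted,
    )
    rc = rc_bray(table, n_null=n_null, seed=int(rng.integers(2**31)))
    bc = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    ids = table.sample_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = nti.bnti.iat[i, j]
            r = rc.iat[i, j]
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "bmntd": nti.observed.iat[i, j],
                    "bnti": b,
                    "bc": bc[i, j],
                    "rcbray": r,
                    "process": classify_assembly(b, r),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ProcessFractions:
    fractions: pd.DataFrame  # index group (+ "pooled"); columns process labels
    bnti_summary: pd.DataFrame  # per group: mean, sd, n_pairs
    kruskal_h: float
    kruskal_p: float
    n_undefined: int


def process_fractions(pairs: pd.DataFrame, groups: pd.Series) -> ProcessFractions:
    """Within-group process fractions and βNTI summaries.

    ``groups`` maps sample id to salinity class; only pairs whose two
    samples share a class contribute to that class's fractions.  The
    Kruskal-Wallis test compares the within-group βNTI distributions.
    """
    pairs = pairs.copy()
    gi = pairs["sample_i"].map(groups)
    gj = pairs["sample_j"].map(groups)
    pairs["group"] = np.where(gi == gj, gi, "between")
    defined = pairs[pairs["process"] != "undefined"]
    n_undefined = int((pairs["process"] == "undefined").sum())

    frac_rows = {}
    bnti_rows = {}
    group_values = []
    group_names = []
    scopes = [g for g in pd.unique(pairs["group"]) if g != "between"] + ["pooled"]
    for scope in scopes:
        sub = defined if scope == "pooled" else defined[defined["group"] == scope]
        if len(sub) == 0:
            continue
        counts = sub["process"].value_counts(normalize=True)
        frac_rows[scope] = {label: float(counts.get(label, 0.0)) for label in PROCESS_LABELS}
        vals = sub["bnti"].dropna()
        bnti_rows[scope] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "n_pairs": int(len(sub)),
        }
        if scope != "pooled" and len(vals) > 0:
            group_values.append(vals.to_numpy())
            group_names.append(scope)
    if len(group_values) >= 2:
        h, p = stats.kruskal(*group_values)
    else:
        h, p = float("nan"), float("nan")
    return ProcessFractions(
        fractions=pd.DataFrame.from_dict(frac_rows, orient="index"),
        bnti_summary=pd.DataFrame.from_dict(bnti_rows, orient="index"),
        kruskal_h=float(h),
        kruskal_p=float(p),
        n_undefined=n_undefined,
    )
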