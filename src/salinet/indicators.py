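"""IndVal indicator-species analysis across salinity classes.

For OTU ``i`` and group ``g``, specificity ``A`` is the mean abundance of
``i`` in ``g`` divided by the sum of its group mean abundances, and
fidelity ``B`` is the fraction of ``g``'s samples containing ``i``.  The
indicator value is ``sqrt(A * B)`` for the group maximising it, with
significance from permutation of the group labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import OtuTable, SalinetError

DEFAULT_INDVAL_MIN = 0.6
DEFAULT_P_MAX = 0.001


def _indval_components(counts: np.ndarray, codes: np.ndarray, n_groups: int):
    """(A, B, stat) matrices of shape (n_groups, n_otus)."""
    means = np.zeros((n_groups, counts.shape[1]))
    occup = np.zeros((n_groups, counts.shape[1]))
    for g in range(n_groups):
        block = counts[codes == g]
        means[g] = block.mean(axis=0)
        occup[g] = (block > 0).mean(axis=0)
    mean_sum = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(mean_sum > 0, means / np.where(mean_sum > 0, mean_sum, 1.0), 0.0)
    stat = np.sqrt(a * occup)
    return a, occup, stat


def indval(
    table: OtuTable,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
    indval_min: float = DEFAULT_INDVAL_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Indicator value of every OTU for its best salinity class.

    Returns one row per OTU: assigned group, specificity ``A``, fidelity
    ``B``, ``indval = sqrt(A*B)``, ``indval_squared = A*B`` (both are
    reported because published thresholds do not always say which scale
    they use), permutation ``p`` and ``is_indicator`` flagging rows with
    ``indval > indval_min`` and ``p <= p_max`` (at 999 permutations the
    smallest attainable p is exactly 1/1000, so the published
    "p < 0.001 after 999 permutations" cut is implemented inclusively).
    """
    labels = pd.Series(list(groups))
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise SalinetError("IndVal needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [u for u, s in zip(uniques, sizes) if s < 2]
        raise SalinetError(f"groups with fewer than 2 samples: {small}")
    counts = table.counts.to_numpy(dtype=float)
    for g, name in enumerate(uniques):
        if counts[codes == g].sum() == 0:
            raise SalinetError(f"group {name!r} has an all-zero table")

    a, b, stat = _indval_components(counts, codes, len(uniques))
    best_group = stat.argmax(axis=0)
    obs = stat.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(counts.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, _, stat_p = _indval_components(counts, perm, len(uniques))
        exceed += stat_p.max(axis=0) >= obs
    p = (1 + exceed) / (1 + n_perm)

    cols = np.arange(counts.shape[1])
    result = pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "group": [uniques[g] for g in best_group],
            "A": a[best_group, cols],
            "B": b[best_group, cols],
            "indval": obs,
            "indval_squared": obs**2,
            "p_value": p,
        }
    ).set_index("otu_id")
    result["is_indicator"] = (result["indval"] > indval_min) & (result["p_value"] <= p_max)
    return result
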