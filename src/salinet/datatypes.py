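"""Core in-memory containers shared by every analysis stage.

The package works on four aligned objects: an OTU count table
(samples x OTUs), a taxonomy table (OTU -> ranked lineage + functional
group), per-sample metadata (salinity and other environmental variables,
coordinates), and a rooted phylogeny whose tips are OTU ids.  All four are
thin wrappers over pandas / dendropy objects so that downstream code can
use ordinary DataFrame and tree operations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

#: Ranks stored for every OTU lineage, coarsest to finest.
LINEAGE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Functional groups recognised for microeukaryotic OTUs.
FUNCTIONAL_GROUPS = ("algae", "protozoa", "fungi", "unassigned")

#: Salinity class bounds (per mille).  A sample is "salt" at >= 8.75,
#: "brackish" at >= 3.535 and < 8.75, "freshwater" below 3.535.
SALT_MIN = 8.75
BRACKISH_MIN = 3.535

SALINITY_CLASSES = ("freshwater", "brackish", "salt")


class SalinetError(ValueError):
    """Base error for invalid inputs to salinet operations."""


@dataclass
class OtuTable:
    """Integer abundance matrix with samples as rows and OTUs as columns.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample id with OTU ids as columns; values are
        nonnegative integers (read counts).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise SalinetError(f"duplicate sample ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise SalinetError(f"duplicate OTU ids: {dups}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise SalinetError("counts must be numeric")
        if np.any(values < 0):
            raise SalinetError("counts must be nonnegative")
        if np.any(values != np.floor(values)):
            raise SalinetError("counts must be integers")
        counts = counts.astype(np.int64)
        counts.index = counts.index.rename("sample_id")
        counts.columns = counts.columns.rename("otu_id")
        self.counts = counts

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised abundances (rows with zero total stay zero)."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts.div(safe, axis=0)

    def occupancy(self) -> pd.Series:
        """Number of samples in which each OTU has count > 0."""
        return (self.counts > 0).sum(axis=0)

    def select_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(otu_ids)].copy())

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids), :].copy())


@dataclass
class TaxonomyTable:
    """OTU -> ranked lineage plus functional group assignment.

    ``data`` is indexed by otu_id with the columns in :data:`LINEAGE_RANKS`
    plus ``functional_group``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SalinetError(f"duplicate otu ids in taxonomy: {dups}")
        missing = [c for c in (*LINEAGE_RANKS, "functional_group") if c not in self.data.columns]
        if missing:
            raise SalinetError(f"taxonomy missing columns: {missing}")
        bad = set(self.data["functional_group"]) - set(FUNCTIONAL_GROUPS)
        if bad:
            raise SalinetError(f"unknown functional groups: {sorted(bad)}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage_string(self, otu_id: str) -> str:
        row = self.data.loc[otu_id, list(LINEAGE_RANKS)]
        return ";".join(str(v) for v in row)

    def lineage_strings(self) -> pd.Series:
        return self.data[list(LINEAGE_RANKS)].astype(str).agg(";".join, axis=1)

    def rank(self, rank: str) -> pd.Series:
        if rank not in LINEAGE_RANKS:
            raise SalinetError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
        return self.data[rank]

    def require_covers(self, otu_ids) -> None:
        missing = [o for o in otu_ids if o not in self.data.index]
        if missing:
            raise SalinetError(f"OTUs missing from taxonomy: {missing}")


@dataclass
class SampleMetadata:
    """Per-sample environmental variables and coordinates.

    ``data`` is indexed by sample id.  ``salinity`` is per mille; latitude
    and longitude are decimal degrees.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SalinetError(f"duplicate sample ids in metadata: {dups}")
        if "salinity" in self.data.columns and (self.data["salinity"] < 0).any():
            raise SalinetError("salinity must be nonnegative")
        if "latitude" in self.data.columns:
            lat = self.data["latitude"]
            if ((lat < -90) | (lat > 90)).any():
                raise SalinetError("latitude out of [-90, 90]")
        if "longitude" in self.data.columns:
            lon = self.data["longitude"]
            if ((lon < -180) | (lon > 180)).any():
                raise SalinetError("longitude out of [-180, 180]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def variables(self, names) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise SalinetError(f"metadata variables not found: {missing}")
        return self.data[list(names)].astype(float)


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths whose tips are OTU ids."""

    tree: dendropy.Tree
    _pdm_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise SalinetError("duplicate tip labels in phylogeny")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise SalinetError("negative branch length in phylogeny")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def patristic_distances(self) -> pd.DataFrame:
        """Tip-to-tip patristic distance matrix (sum of branch lengths)."""
        if self._pdm_cache is None:
            pdm = self.tree.phylogenetic_distance_matrix()
            taxa = [leaf.taxon for leaf in self.tree.leaf_node_iter()]
            labels = [t.label for t in taxa]
            n = len(taxa)
            mat = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d = pdm.patristic_distance(taxa[i], taxa[j])
                    mat[i, j] = mat[j, i] = d
            self._pdm_cache = pd.DataFrame(mat, index=labels, columns=labels)
        return self._pdm_cache

    def require_tips(self, otu_ids) -> None:
        tips = set(self.tip_labels())
        missing = [o for o in otu_ids if o not in tips]
        if missing:
            raise SalinetError(f"OTUs missing from phylogeny tips: {missing}")


def classify_salinity(salinity: float) -> str:
    """Assign a salinity (per mille) to one of the three lake classes.

    Bounds: salt >= 8.75, brackish in [3.535, 8.75), freshwater < 3.535.
    """
    if not np.isfinite(salinity):
        raise SalinetError("salinity must be finite")
    if salinity < 0:
        raise SalinetError(f"salinity must be nonnegative, got {salinity}")
    if salinity >= SALT_MIN:
        return "salt"
    if salinity >= BRACKISH_MIN:
        return "brackish"
    return "freshwater"


def classify_salinity_series(salinity: pd.Series) -> pd.Series:
    """Vectorised :func:`classify_salinity` preserving the index."""
    return salinity.map(classify_salinity).rename("group")
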