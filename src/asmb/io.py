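"""Readers, writers and validated containers for OTU tables, trees and metadata.

Files store OTU tables with OTUs as rows (the common amplicon convention);
in memory the orientation is samples x OTUs, which is what every pairwise
analysis downstream consumes. Trees are Newick with branch lengths; metadata
is a TSV with coordinates, a depth-layer label and the environmental
variables, accompanied by a YAML map assigning each variable to one of the
six canonical environment groups.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from ._matrix import PairwiseMatrix, check_same_labels  # noqa: F401  (re-export)

#: the six environment groups used for composite environmental distances
ENV_GROUPS = (
    "historical_temperature_anomaly",
    "contemporary_climate",
    "aboveground_vegetation",
    "soil_fertility",
    "soil_ph",
    "soil_mineral_content",
)

LAYERS = ("topsoil", "subsoil")


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------
@dataclass
class OtuTable:
    """Non-negative integer read counts, samples x OTUs."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.otu_ids = [str(x) for x in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.size == 0:
            raise ValueError("empty OTU table")
        if not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(counts.astype(float))):
            raise ValueError("non-finite counts")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers (reads)")
        self.counts = counts.astype(np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")

    # -- basic views --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances; errors on a zero-total sample."""
        totals = self.sample_sums()
        if np.any(totals == 0):
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total reads: {bad}")
        return self.counts / totals[:, None]

    def presence(self) -> np.ndarray:
        return self.counts > 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    # -- subsetting ---------------------------------------------------------
    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = [str(s) for s in sample_ids]
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(sample_ids, list(self.otu_ids), self.counts[idx])

    def subset_otus(self, otu_ids) -> "OtuTable":
        otu_ids = [str(o) for o in otu_ids]
        missing = set(otu_ids) - set(self.otu_ids)
        if missing:
            raise KeyError(f"unknown OTUs: {sorted(missing)}")
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(list(self.sample_ids), otu_ids, self.counts[:, idx])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.otu_sums() > 0
        return OtuTable(
            list(self.sample_ids),
            [o for o, k in zip(self.otu_ids, keep) if k],
            self.counts[:, keep],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a tab-separated count table.

    Parameters
    ----------
    path : str or file-like
        TSV whose first column holds OTU ids (default orientation) and whose
        header row holds sample ids, or the transpose with
        ``orientation='samples_as_rows'``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError("empty table")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in OTU table: {exc}") from exc
    if orientation == "otus_as_rows":
        return OtuTable(list(df.columns), list(df.index), values.T)
    elif orientation == "samples_as_rows":
        return OtuTable(list(df.index), list(df.columns), values)
    raise ValueError(f"unknown orientation {orientation!r}")


def write_otu_table(table: OtuTable, path, orientation: str = "otus_as_rows") -> None:
    df = table.to_dataframe()
    if orientation == "otus_as_rows":
        df = df.T
        df.index.name = "otu_id"
    elif orientation == "samples_as_rows":
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------
def read_newick(source) -> TreeNode:
    """Parse a rooted Newick tree, requiring branch lengths and unique tips."""
    if hasattr(source, "read"):
        tree = TreeNode.read(source, format="newick")
    else:
        text = str(source)
        if text.lstrip().startswith("(") and text.rstrip().endswith(";"):
            tree = TreeNode.read(_io.StringIO(text), format="newick")
        else:
            tree = TreeNode.read(text, format="newick")
    tips = [t.name for t in tree.tips()]
    if any(name is None for name in tips):
        raise ValueError("tree has unnamed tips")
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length above {node.name or 'internal node'}")
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name or 'internal node'}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def check_tree_table_ids(table: OtuTable, tree: TreeNode, prune_to_tree: bool = False):
    """Enforce that every table OTU is a tree tip.

    Mismatches are a hard error by default; ``prune_to_tree=True`` instead
    drops the offending OTUs from the table and returns (table, n_dropped) so
    the caller can log the loss explicitly. OTUs are never dropped silently.
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if not missing:
        return table, 0
    if not prune_to_tree:
        raise ValueError(
            f"{len(missing)} OTUs absent from the tree (e.g. {missing[:5]}); "
            "pass prune_to_tree=True to drop them explicitly"
        )
    keep = [o for o in table.otu_ids if o in tips]
    if not keep:
        raise ValueError("no table OTUs present in the tree")
    return table.subset_otus(keep), len(missing)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------
@dataclass
class SampleMetadata:
    """Per-sample site coordinates, depth layer, and environmental variables.

    ``data`` is indexed by sample id with columns ``site_id``, ``longitude``,
    ``latitude``, ``layer`` plus one column per environmental variable;
    ``group_map`` assigns each variable to one of the six canonical groups.
    """

    data: pd.DataFrame
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        req = {"site_id", "longitude", "latitude", "layer"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        lat = self.data["latitude"].to_numpy(dtype=float)
        lon = self.data["longitude"].to_numpy(dtype=float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude out of [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude out of [-180, 180]")
        bad_layers = set(self.data["layer"]) - set(LAYERS)
        if bad_layers:
            raise ValueError(f"unknown layer labels: {sorted(bad_layers)}")
        unmapped = set(self.env_columns) - set(self.group_map)
        if unmapped:
            raise ValueError(f"environmental variables not in group map: {sorted(unmapped)}")
        bad_groups = set(self.group_map.values()) - set(ENV_GROUPS)
        if bad_groups:
            raise ValueError(f"unknown environment groups: {sorted(bad_groups)}")
        env = self.data[self.env_columns].to_numpy(dtype=float)
        if not np.all(np.isfinite(env)):
            raise ValueError("non-finite environmental values")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def env_columns(self) -> list[str]:
        fixed = {"site_id", "longitude", "latitude", "layer"}
        return [c for c in self.data.columns if c not in fixed]

    def groups_present(self) -> set[str]:
        return set(self.group_map[v] for v in self.env_columns)

    def variables_in_group(self, group: str) -> list[str]:
        if group not in ENV_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [v for v in self.env_columns if self.group_map[v] == group]

    def subset_layer(self, layer: str) -> "SampleMetadata":
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return SampleMetadata(self.data[self.data["layer"] == layer].copy(), dict(self.group_map))

    def subset_samples(self, sample_ids) -> "SampleMetadata":
        sample_ids = [str(s) for s in sample_ids]
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return SampleMetadata(self.data.loc[sample_ids].copy(), dict(self.group_map))

    def site_pairing(self) -> dict[str, dict[str, str]]:
        """site_id -> {layer: sample_id} for sites having both layers."""
        pairing = {}
        for sid, row in self.data.iterrows():
            pairing.setdefault(row["site_id"], {})[row["layer"]] = str(sid)
        return {s: d for s, d in pairing.items() if set(d) == set(LAYERS)}


def read_metadata(path, group_map_path, require_all_groups: bool = True) -> SampleMetadata:
    """Read the sample metadata TSV and its variable-to-group YAML map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    else:
        if not {"site_id", "layer"} <= set(df.columns):
            raise ValueError("metadata needs a sample_id column or site_id+layer columns")
        df.index = df["site_id"].astype(str) + "." + df["layer"].astype(str)
        df.index.name = "sample_id"
    with open(group_map_path) as fh:
        group_map = yaml.safe_load(fh)
    if not isinstance(group_map, dict):
        raise ValueError("group map must be a mapping of variable -> group")
    md = SampleMetadata(df, {str(k): str(v) for k, v in group_map.items()})
    if require_all_groups:
        absent = set(ENV_GROUPS) - md.groups_present()
        if absent:
            raise ValueError(f"environment groups with no variables: {sorted(absent)}")
    return md


def write_metadata(md: SampleMetadata, path, group_map_path=None) -> None:
    df = md.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if group_map_path is not None:
        with open(group_map_path, "w") as fh:
            yaml.safe_dump(md.group_map, fh, sort_keys=True)
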