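"""Parcellation region table: the 98-node whole-brain fixture and I/O.

The default fixture combines 68 Desikan-Killiany cortical parcels,
10 bilateral subcortical structures, 8 hippocampal subregion groups
(CA1, CA3/4, subicular complex, GC-DG per hemisphere) and 12 amygdala
nuclei (LA, BA, ABA, CoA, CeA, CAT per hemisphere; medial nucleus
excluded), 98 regions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "midline")
CATEGORIES = ("cortical", "subcortical", "hippocampal_subfield", "amygdala_nucleus")
FAMILIES = ("none", "hippocampus", "amygdala")

REGION_COLUMNS = ["region_index", "name", "hemisphere", "category", "family", "lobe"]

# Desikan-Killiany cortical parcels with lobe assignment (34 per hemisphere).
_DK_PARCELS = [
    ("superiorfrontal", "frontal"),
    ("rostralmiddlefrontal", "frontal"),
    ("caudalmiddlefrontal", "frontal"),
    ("parsopercularis", "frontal"),
    ("parstriangularis", "frontal"),
    ("parsorbitalis", "frontal"),
    ("lateralorbitofrontal", "frontal"),
    ("medialorbitofrontal", "frontal"),
    ("precentral", "frontal"),
    ("paracentral", "frontal"),
    ("frontalpole", "frontal"),
    ("superiorparietal", "parietal"),
    ("inferiorparietal", "parietal"),
    ("supramarginal", "parietal"),
    ("postcentral", "parietal"),
    ("precuneus", "parietal"),
    ("superiortemporal", "temporal"),
    ("middletemporal", "temporal"),
    ("inferiortemporal", "temporal"),
    ("bankssts", "temporal"),
    ("fusiform", "temporal"),
    ("transversetemporal", "temporal"),
    ("entorhinal", "temporal"),
    ("temporalpole", "temporal"),
    ("parahippocampal", "temporal"),
    ("lateraloccipital", "occipital"),
    ("lingual", "occipital"),
    ("cuneus", "occipital"),
    ("pericalcarine", "occipital"),
    ("rostralanteriorcingulate", "cingulate"),
    ("caudalanteriorcingulate", "cingulate"),
    ("posteriorcingulate", "cingulate"),
    ("isthmuscingulate", "cingulate"),
    ("insula", "insula"),
]

_SUBCORTICAL = ["thalamus", "caudate", "putamen", "pallidum", "accumbens"]

_HIPPOCAMPAL_SUBFIELDS = ["CA1", "CA3/4", "subicular_complex", "GC-DG"]

_AMYGDALA_NUCLEI = ["LA", "BA", "ABA", "CoA", "CeA", "CAT"]


@dataclass
class RegionTable:
    """Ordered parcellation with hemisphere/category/family labels.

    Region order defines the row/column order of every connectivity
    matrix bound to this table.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        idx = df["region_index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(df))):
            raise ValueError("region_index values must be unique and contiguous from 0")
        if df["name"].duplicated().any():
            raise ValueError("duplicate region names")
        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {bad_hemi}")
        bad_cat = set(df["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown category labels: {bad_cat}")
        bad_fam = set(df["family"]) - set(FAMILIES)
        if bad_fam:
            raise ValueError(f"unknown family labels: {bad_fam}")
        self.table = df.sort_values("region_index").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionTable):
            return NotImplemented
        return self.table.equals(other.table)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def family_indices(self, family: str) -> np.ndarray:
        """0-based region indices belonging to a subregion family."""
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        return self.table.index[self.table["family"] == family].to_numpy()

    def index_of(self, name: str) -> int:
        hits = self.table.index[self.table["name"] == name]
        if len(hits) != 1:
            raise KeyError(f"region {name!r} not found")
        return int(hits[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path))


def default_region_table() -> RegionTable:
    """Assemble the default 98-region parcellation fixture."""
    rows = []
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name, lobe in _DK_PARCELS:
            rows.append((f"{prefix}_{name}", hemi, "cortical", "none", lobe))
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name in _SUBCORTICAL:
            rows.append((f"{prefix}_{name}", hemi, "subcortical", "none", "subcortical"))
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name in _HIPPOCAMPAL_SUBFIELDS:
            rows.append(
                (f"{prefix}_hippocampus_{name}", hemi, "hippocampal_subfield", "hippocampus", "limbic")
            )
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name in _AMYGDALA_NUCLEI:
            rows.append((f"{prefix}_amygdala_{name}", hemi, "amygdala_nucleus", "amygdala", "limbic"))
    df = pd.DataFrame(rows, columns=["name", "hemisphere", "category", "family", "lobe"])
    df.insert(0, "region_index", np.arange(len(df)))
    return RegionTable(df)


def generic_region_table(n_nodes: int) -> RegionTable:
    """Minimal synthetic parcellation for arbitrary node counts.

    First half of the nodes is labeled left hemisphere, second half right
    (odd counts put the extra node on the right).  Used by the simulator
    when ``n_nodes`` differs from the default 98.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    half = n_nodes // 2
    rows = []
    for i in range(n_nodes):
        hemi = "left" if i < half else "right"
        rows.append((i, f"node{i:03d}", hemi, "cortical", "none", "synthetic"))
    return RegionTable(pd.DataFrame(rows, columns=REGION_COLUMNS))
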