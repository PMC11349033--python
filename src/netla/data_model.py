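"""Core domain types for parcellated connectomes.

A connectome here is the vector of Fisher-z transformed Pearson correlations
between the mean BOLD time courses of every unordered pair of parcels (ROIs).
With ``P`` parcels there are ``E = P(P-1)/2`` edges; a parcel-to-network
partition groups edges into ``B = N(N+1)/2`` network blocks (within-network
and between-network edge sets), the unit of enrichment inference.

Edge ordering is fixed to lower-triangle row-major: edges are enumerated by
increasing row index ``i`` and, within a row, increasing column ``j < i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

EDGE_ORDER = "lower_tri_row_major"
RESULTS_SCHEMA_VERSION = 1

__all__ = [
    "EdgeIndex",
    "NetworkPartition",
    "ConnectomeDataset",
    "BlockMap",
    "build_edge_index",
    "fisher_z_connectivity",
    "build_block_map",
    "read_partition",
    "write_partition",
    "read_dataset",
    "write_dataset",
    "read_edges_csv",
    "write_edges_csv",
    "write_results",
    "read_results",
]

# |r| is clipped to this before atanh so perfectly (anti)correlated rows map
# to a large finite z instead of +/-inf.
_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class EdgeIndex:
    """Bijection between edge ids and unordered parcel pairs.

    Edge ``e`` corresponds to the pair ``(i, j)`` with ``0 <= j < i < P``;
    ``e = i(i-1)/2 + j``.
    """

    parcel_count: int

    @property
    def edge_count(self) -> int:
        p = self.parcel_count
        return p * (p - 1) // 2

    def pair_of(self, e):
        """Map edge id(s) to ``(i, j)`` with ``j < i``. Vectorized."""
        e = np.asarray(e)
        if np.any(e < 0) or np.any(e >= self.edge_count):
            raise IndexError("edge id out of range")
        # invert e = i(i-1)/2 + j
        i = ((1.0 + np.sqrt(1.0 + 8.0 * e)) / 2.0).astype(np.int64)
        # guard against float rounding at triangular-number boundaries
        i = np.where(i * (i - 1) // 2 > e, i - 1, i)
        i = np.where((i + 1) * i // 2 <= e, i + 1, i)
        j = e - i * (i - 1) // 2
        if np.ndim(e) == 0:
            return int(i), int(j)
        return i, j

    def index_of(self, i, j):
        """Map parcel pair(s) ``(i, j)``, ``j < i``, to edge id(s)."""
        i = np.asarray(i)
        j = np.asarray(j)
        if np.any(j >= i) or np.any(j < 0) or np.any(i >= self.parcel_count):
            raise IndexError("require 0 <= j < i < parcel_count")
        e = i * (i - 1) // 2 + j
        if np.ndim(i) == 0 and np.ndim(j) == 0:
            return int(e)
        return e

    def pairs(self):
        """Arrays ``(i, j)`` for all edges in canonical order."""
        return np.tril_indices(self.parcel_count, k=-1)


def build_edge_index(parcel_count: int) -> EdgeIndex:
    """Create the canonical edge index for ``parcel_count`` parcels."""
    if parcel_count < 2:
        raise ValueError(f"parcel_count must be >= 2, got {parcel_count}")
    return EdgeIndex(int(parcel_count))


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of each parcel to exactly one functional network.

    ``labels`` are 1-based network ids, contiguous ``1..N``; ``names`` gives
    one display name per network. An "unspecified" network, if present, is an
    ordinary network in block enumeration.
    """

    parcel_count: int
    labels: np.ndarray  # shape (P,), int, values in 1..N
    names: tuple = ()

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.parcel_count,):
            raise ValueError(
                f"labels has shape {labels.shape}, expected ({self.parcel_count},)"
            )
        uniq = np.unique(labels)
        n = uniq.size
        if n < 2:
            raise ValueError("a partition needs at least 2 networks")
        if uniq[0] != 1 or uniq[-1] != n:
            raise ValueError("network ids must be contiguous 1..N")
        if self.names:
            if len(self.names) != n:
                raise ValueError(f"{len(self.names)} names for {n} networks")
            object.__setattr__(self, "names", tuple(self.names))
        else:
            object.__setattr__(
                self, "names", tuple(f"Net{k}" for k in range(1, n + 1))
            )

    @property
    def network_count(self) -> int:
        return len(self.names)

    @property
    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.network_count + 1)[1:]


@dataclass
class ConnectomeDataset:
    """Per-subject edge vectors with phenotypes for one scan day."""

    subject_ids: np.ndarray  # (n,) str
    family_ids: np.ndarray  # (n,) str
    ages: np.ndarray  # (n,) float, years
    day: int  # 1 or 2
    edges: np.ndarray  # (n, E) float Fisher-z values
    parcel_count: int

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        self.family_ids = np.asarray(self.family_ids, dtype=str)
        self.ages = np.asarray(self.ages, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        n = self.subject_ids.shape[0]
        index = build_edge_index(self.parcel_count)
        if self.edges.shape != (n, index.edge_count):
            raise ValueError(
                f"edges has shape {self.edges.shape}, expected "
                f"({n}, {index.edge_count}) for P={self.parcel_count}"
            )
        if self.family_ids.shape != (n,) or self.ages.shape != (n,):
            raise ValueError("phenotype arrays must have one entry per subject")
        if not np.all(np.isfinite(self.ages)):
            raise ValueError("ages must be finite (no missing values)")
        if not np.all(np.isfinite(self.edges)):
            raise ValueError("edge values must be finite")
        if self.day not in (1, 2):
            raise ValueError("day must be 1 or 2")

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.shape[0]

    @property
    def edge_count(self) -> int:
        return self.edges.shape[1]


@dataclass(frozen=True)
class BlockMap:
    """Grouping of edges into network blocks.

    Blocks are unordered network pairs ``(a, b)``, ``a <= b`` (1-based),
    enumerated row-major: (1,1), (1,2), ..., (1,N), (2,2), ... Within-network
    block ``(a, a)`` has ``n_a(n_a-1)/2`` edges; between-network ``(a, b)``
    has ``n_a * n_b``.
    """

    network_count: int
    block_of_edge: np.ndarray  # (E,) block id in [0, B)
    block_pairs: np.ndarray  # (B, 2) 1-based network pairs, a <= b

    @property
    def block_count(self) -> int:
        n = self.network_count
        return n * (n + 1) // 2

    @property
    def edge_count(self) -> int:
        return self.block_of_edge.shape[0]

    @property
    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.block_of_edge, minlength=self.block_count)

    def block_id(self, a: int, b: int) -> int:
        """Block id for the unordered 1-based network pair ``(a, b)``."""
        a, b = min(a, b), max(a, b)
        n = self.network_count
        if not (1 <= a <= b <= n):
            raise IndexError("network ids out of range")
        # row-major upper-triangle (including diagonal) enumeration
        return (a - 1) * n - (a - 1) * a // 2 + (b - a) + (a - 1)

    def edges_in_block(self, block: int) -> np.ndarray:
        return np.nonzero(self.block_of_edge == block)[0]


def build_block_map(partition: NetworkPartition, index: EdgeIndex) -> BlockMap:
    """Assign every edge to its network block."""
    if partition.parcel_count != index.parcel_count:
        raise ValueError(
            f"partition has {partition.parcel_count} parcels, "
            f"edge index has {index.parcel_count}"
        )
    n = partition.network_count
    ii, jj = index.pairs()
    la = partition.labels[ii]
    lb = partition.labels[jj]
    a = np.minimum(la, lb)
    b = np.maximum(la, lb)
    block = (a - 1) * n - (a - 1) * a // 2 + (b - a) + (a - 1)
    pairs = np.array(
        [(x, y) for x in range(1, n + 1) for y in range(x, n + 1)], dtype=np.int64
    )
    return BlockMap(n, block.astype(np.int64), pairs)


def fisher_z_connectivity(timeseries: np.ndarray) -> np.ndarray:
    """Edge vector of Fisher-z correlations from a P x T time-series matrix.

    Entry ``e`` is ``atanh(r)`` of the Pearson correlation between the time
    courses of parcels ``pair_of(e)``, with ``r`` clipped to ``+/-(1 - 1e-7)``
    so degenerate perfect correlations stay finite.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D P x T array")
    p, t = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"parcel {bad[0]} has zero-variance time course")
    r = np.corrcoef(ts)
    ii, jj = np.tril_indices(p, k=-1)
    return np.arctanh(np.clip(r[ii, jj], -_R_CLIP, _R_CLIP))


# ---------------------------------------------------------------------------
# On-disk formats


def write_partition(partition: NetworkPartition, path) -> None:
    """Write a partition as TSV: parcel_id, network_id, network_name."""
    df = pd.DataFrame(
        {
            "parcel_id": np.arange(1, partition.parcel_count + 1),
            "network_id": partition.labels,
            "network_name": [partition.names[l - 1] for l in partition.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t")
    for col in ("parcel_id", "network_id", "network_name"):
        if col not in df.columns:
            raise ValueError(f"partition file {path}: missing column '{col}'")
    if df["network_id"].isna().any():
        line = int(df.index[df["network_id"].isna()][0]) + 2
        raise ValueError(f"partition file {path}: missing network id at line {line}")
    df = df.sort_values("parcel_id")
    labels = df["network_id"].to_numpy(dtype=np.int64)
    names_map = {}
    for nid, nname in zip(labels, df["network_name"]):
        names_map.setdefault(int(nid), str(nname))
    try:
        names = tuple(names_map[k] for k in range(1, labels.max() + 1))
    except KeyError as err:
        raise ValueError(
            f"partition file {path}: network ids not contiguous 1..N"
        ) from err
    return NetworkPartition(len(labels), labels, names)


def write_dataset(dataset: ConnectomeDataset, edges_path, phenotypes_path) -> None:
    """Write edges to an HDF5 container and phenotypes to CSV."""
    with h5py.File(edges_path, "w") as f:
        d = f.create_dataset("edges", data=dataset.edges)
        d.attrs["parcel_count"] = dataset.parcel_count
        d.attrs["edge_order"] = EDGE_ORDER
        d.attrs["day"] = dataset.day
    pd.DataFrame(
        {
            "subject_id": dataset.subject_ids,
            "family_id": dataset.family_ids,
            "age": dataset.ages,
            "day": dataset.day,
        }
    ).to_csv(phenotypes_path, index=False)


def read_dataset(edges_path, phenotypes_path) -> ConnectomeDataset:
    with h5py.File(edges_path, "r") as f:
        if "edges" not in f:
            raise ValueError(f"{edges_path}: missing 'edges' dataset")
        d = f["edges"]
        edges = d[...]
        parcel_count = int(d.attrs["parcel_count"])
        day = int(d.attrs.get("day", 1))
        order = d.attrs.get("edge_order", EDGE_ORDER)
        if isinstance(order, bytes):
            order = order.decode()
        if order != EDGE_ORDER:
            raise ValueError(f"{edges_path}: unsupported edge order '{order}'")
    pheno = pd.read_csv(phenotypes_path, dtype={"subject_id": str, "family_id": str})
    for col in ("subject_id", "family_id", "age"):
        if col not in pheno.columns:
            raise ValueError(f"{phenotypes_path}: missing column '{col}'")
    missing = pheno["family_id"].isna() | (pheno["family_id"].astype(str) == "")
    if missing.any():
        line = int(pheno.index[missing][0]) + 2
        raise ValueError(f"{phenotypes_path}: missing family id at line {line}")
    if pheno["age"].isna().any():
        line = int(pheno.index[pheno["age"].isna()][0]) + 2
        raise ValueError(f"{phenotypes_path}: missing age at line {line}")
    if "day" in pheno.columns and pheno["day"].nunique() == 1:
        day = int(pheno["day"].iloc[0])
    return ConnectomeDataset(
        subject_ids=pheno["subject_id"].to_numpy(dtype=str),
        family_ids=pheno["family_id"].to_numpy(dtype=str),
        ages=pheno["age"].to_numpy(dtype=float),
        day=day,
        edges=edges,
        parcel_count=parcel_count,
    )


def write_edges_csv(edges: np.ndarray, path) -> None:
    """Wide-CSV alternative to the HDF5 container (12 significant digits)."""
    np.savetxt(path, np.atleast_2d(edges), fmt="%.12g", delimiter=",")


def read_edges_csv(path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as err:
        raise ValueError(f"{path}: malformed edge CSV ({err})") from err
    return arr


def write_results(results: dict, path) -> None:
    """Write an analysis-results JSON with a schema version field."""
    payload = {"schema_version": RESULTS_SCHEMA_VERSION}
    payload.update(results)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, default=_json_default)


def read_results(path) -> dict:
    with open(path) as f:
        return json.load(f)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
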