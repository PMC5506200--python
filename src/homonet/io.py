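"""Readers and writers for the on-disk formats.

Tabular data is TSV (spreadsheet-inspectable), nested reports are JSON,
images are NIfTI.  Strongest links and partitions can be exported in the
plain-text .node / .edge convention used by 3D brain-network viewers.
Every table written here carries a provenance comment header (version,
seed, config hash) that the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graph import Partition
from .nodes import NodeSet
from .synthetic import SubjectTimeSeries

__all__ = [
    "InvalidPairingError",
    "read_nodeset",
    "write_nodeset",
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "read_paradigm_events",
    "write_paradigm_events",
    "write_node_edge_files",
    "provenance_header",
]


class InvalidPairingError(ValueError):
    """A pair id in a node table is used by a number of nodes other than 2."""


def provenance_header(seed=None, config_hash=None) -> str:
    parts = [f"# homonet v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return " ".join(parts)


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, seed=None, cfg_hash=None, index=False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --- node tables ------------------------------------------------------------


def write_nodeset(nodes: NodeSet, path, **prov) -> None:
    pair_id = [""] * nodes.n_nodes
    for k, (i, j) in enumerate(nodes.pair_map, start=1):
        pair_id[i] = pair_id[j] = f"P{k:02d}"
    df = pd.DataFrame(
        {
            "label": nodes.labels,
            "x": nodes.centers_mm[:, 0],
            "y": nodes.centers_mm[:, 1],
            "z": nodes.centers_mm[:, 2],
            "hemisphere": nodes.hemisphere,
            "pair_id": pair_id,
        }
    )
    _write_tsv(df, path, **prov)


def read_nodeset(path) -> NodeSet:
    """Node table TSV -> NodeSet.

    Required columns: label, x, y, z, hemisphere, pair_id (empty for
    unpaired nodes); every non-empty pair id must appear on exactly two
    rows, which define a homotopic pair.
    """
    df = _read_tsv(path, dtype={"pair_id": str}, keep_default_na=False)
    required = {"label", "x", "y", "z", "hemisphere", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"node table {path} missing columns: {sorted(missing)}")
    pairs: list[tuple[int, int]] = []
    for pid, grp in df.groupby("pair_id"):
        if pid == "":
            continue
        if len(grp) != 2:
            raise InvalidPairingError(
                f"pair_id {pid!r} appears {len(grp)} times (must be exactly 2)"
            )
        pairs.append((int(grp.index[0]), int(grp.index[1])))
    pairs.sort()
    return NodeSet(
        labels=tuple(df["label"].astype(str)),
        centers_mm=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        pair_map=tuple(pairs),
    )


# --- time series ------------------------------------------------------------


def write_timeseries(ts: SubjectTimeSeries, outdir, seed=None) -> None:
    """Write one subject: data TSV (region x scan), confounds TSV, sidecar
    JSON (tr_s, subject_id)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = outdir / ts.subject_id
    _write_tsv(pd.DataFrame(ts.data), f"{base}_timeseries.tsv", seed=seed, index=True)
    _write_tsv(ts.confounds, f"{base}_confounds.tsv", seed=seed)
    with open(f"{base}.json", "w") as fh:
        json.dump({"tr_s": ts.tr_s, "subject_id": ts.subject_id, "seed": seed}, fh, indent=1)


def read_timeseries(outdir, subject_id: str) -> SubjectTimeSeries:
    base = Path(outdir) / subject_id
    with open(f"{base}.json") as fh:
        meta = json.load(fh)
    data = _read_tsv(f"{base}_timeseries.tsv", index_col=0).to_numpy(dtype=float)
    confounds = _read_tsv(f"{base}_confounds.tsv")
    return SubjectTimeSeries(
        data=data, tr_s=float(meta["tr_s"]), confounds=confounds, subject_id=subject_id
    )


# --- matrices and partitions ------------------------------------------------


def write_matrix(M: np.ndarray, path, labels=None, **prov) -> None:
    df = pd.DataFrame(np.asarray(M, dtype=float))
    if labels is not None:
        df.index = list(labels)
        df.columns = list(labels)
    _write_tsv(df, path, index=True, **prov)


def read_matrix(path) -> np.ndarray:
    return _read_tsv(path, index_col=0).to_numpy(dtype=float)


def write_partition(partition: Partition, path, labels=None, **prov) -> None:
    n = len(partition.assignment)
    df = pd.DataFrame(
        {
            "node": list(labels) if labels is not None else list(range(n)),
            "module": partition.assignment,
        }
    )
    _write_tsv(df, path, **prov)


def read_partition(path, W: np.ndarray | None = None, gamma: float = 1.0) -> Partition:
    from .graph import modularity_q

    df = _read_tsv(path)
    a = df["module"].to_numpy(dtype=int)
    q = modularity_q(W, a, gamma=gamma) if W is not None else 0.0
    return Partition(assignment=a, q_value=q)


# --- paradigm event files ---------------------------------------------------


def write_paradigm_events(paradigm, path, **prov) -> None:
    from .design import TaskParadigm  # noqa: F401  (type only)

    df = pd.DataFrame(
        {
            "onset": [b.onset_s for b in paradigm.blocks],
            "duration": [b.duration_s for b in paradigm.blocks],
            "condition": [b.condition for b in paradigm.blocks],
        }
    )
    _write_tsv(df, path, **prov)


def read_paradigm_events(path, tr_s: float, total_duration_s: float | None = None):
    """Event TSV (onset, duration, condition) -> TaskParadigm; the run
    length defaults to the last offset rounded up to a whole scan."""
    from .design import Block, TaskParadigm

    df = _read_tsv(path)
    blocks = tuple(
        Block(float(r.onset), float(r.duration), str(r.condition))
        for r in df.itertuples()
    )
    if total_duration_s is None:
        last = max(b.onset_s + b.duration_s for b in blocks)
        total_duration_s = float(np.ceil(last / tr_s) * tr_s)
    return TaskParadigm(blocks=blocks, total_duration_s=total_duration_s, tr_s=tr_s)


# --- brain-network viewer export --------------------------------------------


def write_node_edge_files(
    nodes: NodeSet,
    W: np.ndarray,
    partition: Partition,
    basename,
) -> None:
    """Export .node (x y z color size label) and .edge (square matrix)
    text files; color = module id + 1, size = node strength."""
    from .graph import strength

    base = Path(basename)
    s = strength(W)
    with open(base.with_suffix(".node"), "w") as fh:
        for i in range(nodes.n_nodes):
            x, y, z = nodes.centers_mm[i]
            fh.write(
                f"{x:g}\t{y:g}\t{z:g}\t{partition.assignment[i] + 1}\t"
                f"{s[i]:.4f}\t{nodes.labels[i]}\n"
            )
    np.savetxt(base.with_suffix(".edge"), W, fmt="%.6f", delimiter="\t")
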