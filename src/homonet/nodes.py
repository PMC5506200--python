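"""The network's vertex universe: labeled regions with MNI centers,
hemisphere tags and a homotopic-pair map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NodeSet", "default_nodeset"]


@dataclass(frozen=True)
class NodeSet:
    """Region labels, MNI (x, y, z) centers, hemisphere tags (L/R/M) and a
    list of (i, j) index pairs marking homotopic homologs."""

    labels: tuple[str, ...]
    centers_mm: np.ndarray  # (n, 3)
    hemisphere: tuple[str, ...]
    pair_map: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_mm, dtype=float)
        object.__setattr__(self, "centers_mm", centers)
        n = len(self.labels)
        if centers.shape != (n, 3):
            raise ValueError(f"centers_mm must be ({n}, 3), got {centers.shape}")
        if not np.all(np.isfinite(centers)):
            raise ValueError("centers_mm contains non-finite values")
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere tags must match node count")
        for h in self.hemisphere:
            if h not in ("L", "R", "M"):
                raise ValueError(f"hemisphere tag must be L, R or M, got {h!r}")
        used: set[int] = set()
        for i, j in self.pair_map:
            if i == j:
                raise ValueError(f"pair ({i}, {j}) links a node to itself")
            if i in used or j in used:
                raise ValueError(f"node index reused across pairs: ({i}, {j})")
            used.update((i, j))
            if {self.hemisphere[i], self.hemisphere[j]} != {"L", "R"}:
                raise ValueError(
                    f"paired nodes {self.labels[i]}/{self.labels[j]} must lie "
                    "on opposite hemispheres"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_map)

    @property
    def paired_indices(self) -> tuple[int, ...]:
        out: list[int] = []
        for i, j in self.pair_map:
            out.extend((i, j))
        return tuple(sorted(out))

    @property
    def unpaired_indices(self) -> tuple[int, ...]:
        paired = set(self.paired_indices)
        return tuple(i for i in range(self.n_nodes) if i not in paired)

    def homolog(self, i: int) -> int | None:
        """Index of node i's homotopic homolog, or None if unpaired."""
        for a, b in self.pair_map:
            if a == i:
                return b
            if b == i:
                return a
        return None


# Schematic MNI placements for the motor network: 12 homotopic pairs spanning
# the cranial-caudal axis plus 4 unpaired regions (left M1, left S1, left
# thalamus, cerebellar vermis — the unilateral activations for right-foot
# movement).  Coordinates are schematic, chosen to mirror across x = 0 and to
# keep every 3 mm sphere disjoint; they are not measured activation peaks.
_PAIRED = [
    # (label stem, |x|, y, z)
    ("SFG", 22, 6, 64),
    ("SMA", 8, -12, 58),
    ("PMd", 26, -10, 56),
    ("CMA", 8, -2, 44),
    ("SPL", 20, -52, 62),
    ("PMv", 52, 4, 30),
    ("IPC", 46, -40, 48),
    ("S2", 54, -22, 18),
    ("aINS", 38, 10, 2),
    ("CAU", 14, 8, 10),
    ("PUT", 26, -4, 2),
    ("CER", 22, -54, -24),
]
_UNPAIRED = [
    ("M1_L", (-8, -32, 66), "L"),
    ("S1_L", (-12, -42, 70), "L"),
    ("THA_L", (-10, -20, 8), "L"),
    ("VERMIS", (0, -60, -18), "M"),
]


def default_nodeset() -> NodeSet:
    """The 28-region motor network: 12 mirrored pairs + 4 unpaired nodes."""
    labels: list[str] = []
    centers: list[tuple[float, float, float]] = []
    hemis: list[str] = []
    pairs: list[tuple[int, int]] = []
    for stem, x, y, z in _PAIRED:
        i = len(labels)
        labels.extend((f"{stem}_L", f"{stem}_R"))
        centers.extend(((-x, y, z), (x, y, z)))
        hemis.extend(("L", "R"))
        pairs.append((i, i + 1))
    for label, c, h in _UNPAIRED:
        labels.append(label)
        centers.append(c)
        hemis.append(h)
    return NodeSet(
        labels=tuple(labels),
        centers_mm=np.array(centers, dtype=float),
        hemisphere=tuple(hemis),
        pair_map=tuple(pairs),
    )
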