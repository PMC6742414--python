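"""Cell partitions: the output type of OLMC and of the full pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


@dataclass
class Partition:
    """A cell -> cluster-label mapping with provenance.

    Parameters
    ----------
    labels
        Mapping from cell identifier to integer cluster label. Every cell
        carries exactly one label.
    iteration_found
        Mapping from cluster label to the pipeline iteration in which the
        cluster was frozen. Standalone clusterings (plain OLMC) use 1 for
        every label.
    merged_from
        Optional provenance for the dendrogram merge step: new label ->
        tuple of pre-merge labels.
    """

    labels: dict[str, int]
    iteration_found: dict[int, int] = field(default_factory=dict)
    merged_from: dict[int, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        for lbl in present:
            self.iteration_found.setdefault(lbl, 1)
        extra = set(self.iteration_found) - present
        for lbl in extra:
            del self.iteration_found[lbl]

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def cluster_labels(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.labels.values())))

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> tuple[str, ...]:
        """Cell ids carrying ``label``, in insertion order."""
        return tuple(c for c, l in self.labels.items() if l == label)

    def labels_for(self, cell_ids: Iterable[str]) -> np.ndarray:
        """Integer label array aligned with ``cell_ids``."""
        return np.array([self.labels[c] for c in cell_ids], dtype=int)

    def as_mapping(self) -> Mapping[str, int]:
        return dict(self.labels)
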