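"""Named gene sets used by the trajectory stage.

The two built-in panels follow the study design for *Xenopus laevis*
gastrulae: the RA metabolic/transport network (the transcriptional
feedback machinery that counteracts retinoic-acid perturbations) and a
panel of direct *hox* targets (the phenotypic readout).  Homeolog
suffixes ``.L``/``.S`` refer to the long and short chromosome copies of
the allotetraploid genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

#: Feedback machinery: RA synthesis, degradation, binding and transport.
RA_NETWORK_GENES: tuple[str, ...] = (
    "aldh1a2.L",
    "aldh1a3.L",
    "crabp2.L",
    "crabp2.S",
    "cyp26a1.L",
    "cyp26a1.S",
    "cyp26c1.L",
    "cyp26c1.S",
    "dhrs3.L",
    "rbp1.L",
    "rdh10.L",
    "rdh10.S",
    "rdh13.L",
    "rdh14.L",
    "sdr16c5.L",
    "stra6.L",
)

#: Phenotypic outcome panel: direct hox targets of RA signaling.
HOX_GENES: tuple[str, ...] = (
    "hoxa1.L",
    "hoxa1.S",
    "hoxa3.S",
    "hoxb1.S",
    "hoxb4.S",
    "hoxd4.L",
)


@dataclass
class GeneSetCatalog:
    """Mapping from set labels to gene-id lists.

    Construct with :meth:`default` to get the built-in ``ra_network``
    (16 ids) and ``hox`` (6 ids) panels.
    """

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "GeneSetCatalog":
        return cls({"ra_network": RA_NETWORK_GENES, "hox": HOX_GENES})

    def __getitem__(self, label: str) -> tuple[str, ...]:
        return self.sets[label]

    def __contains__(self, label: str) -> bool:
        return label in self.sets

    def labels(self) -> list[str]:
        return list(self.sets)

    def add(self, label: str, gene_ids) -> None:
        ids = tuple(gene_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids in gene set {label!r}")
        self.sets[label] = ids

    @classmethod
    def from_files(cls, paths: dict[str, str | Path]) -> "GeneSetCatalog":
        """Load sets from one-id-per-line text files, keyed by label."""
        cat = cls()
        for label, path in paths.items():
            text = Path(path).read_text()
            ids = [line.strip() for line in text.splitlines() if line.strip()]
            if not ids:
                raise ValueError(f"gene-set file {path} is empty")
            cat.add(label, ids)
        return cat

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, ids in self.sets.items():
            (directory / f"{label}.txt").write_text("\n".join(ids) + "\n")
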