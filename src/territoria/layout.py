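"""Genome layouts for polyploid chromosome sets.

A layout describes an allopolyploid genome as an ordered list of chromosomes,
each belonging to a subgenome (e.g. the A/B/D subgenomes of hexaploid bread
wheat) and to a homeolog group (chromosome 1A, 1B and 1D form group 1).  All
binned data structures (contact matrices, insulation tracks) reference a
layout and its fixed bin grid.

Coordinates are 0-based half-open throughout; the last bin of a chromosome
may be shorter than ``bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chromosome", "GenomeLayout", "make_layout"]

#: default subgenome letters, wheat-style
_SUBGENOME_LETTERS = "ABDEFGH"


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, subgenome label, homeolog group and length (bp)."""

    name: str
    subgenome: str
    homeolog_group: int
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")


@dataclass
class GenomeLayout:
    """Ordered chromosome set with a fixed bin grid.

    Parameters
    ----------
    subgenome_labels
        Short labels, one per subgenome (e.g. ``["A", "B", "D"]``).
    chromosomes
        Ordered chromosomes.  Homeolog groups must contain at most one
        chromosome per subgenome.
    bin_size
        Width of the bin grid in bp.
    """

    subgenome_labels: list[str]
    chromosomes: list[Chromosome]
    bin_size: int
    _bins: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        seen: set[tuple[str, int]] = set()
        for c in self.chromosomes:
            if c.subgenome not in self.subgenome_labels:
                raise ValueError(f"chromosome {c.name}: unknown subgenome {c.subgenome!r}")
            key = (c.subgenome, c.homeolog_group)
            if key in seen:
                raise ValueError(
                    f"homeolog group {c.homeolog_group} has more than one "
                    f"chromosome in subgenome {c.subgenome}"
                )
            seen.add(key)

    # -- bin grid -----------------------------------------------------------

    def n_bins_of(self, chrom: Chromosome) -> int:
        return -(-chrom.length // self.bin_size)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.chromosomes)

    @property
    def bins(self) -> pd.DataFrame:
        """Bin table: chrom, start, end (0-based half-open), global index."""
        if self._bins is None:
            rows = []
            for c in self.chromosomes:
                starts = np.arange(0, c.length, self.bin_size)
                ends = np.minimum(starts + self.bin_size, c.length)
                rows.append(pd.DataFrame({"chrom": c.name, "start": starts, "end": ends}))
            bins = pd.concat(rows, ignore_index=True)
            bins.index.name = "bin"
            object.__setattr__(self, "_bins", bins)
        return self._bins

    def chrom_slices(self) -> dict[str, slice]:
        """Global-bin-index slice of each chromosome, in layout order."""
        out: dict[str, slice] = {}
        lo = 0
        for c in self.chromosomes:
            n = self.n_bins_of(c)
            out[c.name] = slice(lo, lo + n)
            lo += n
        return out

    def chrom_by_name(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def is_homeolog_pair(self, a: str, b: str) -> bool:
        """True iff chromosomes share a homeolog group but not a subgenome."""
        ca, cb = self.chrom_by_name(a), self.chrom_by_name(b)
        return ca.homeolog_group == cb.homeolog_group and ca.subgenome != cb.subgenome

    def with_bin_size(self, bin_size: int) -> "GenomeLayout":
        return GenomeLayout(list(self.subgenome_labels), list(self.chromosomes), bin_size)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [c.name for c in self.chromosomes],
                "subgenome": [c.subgenome for c in self.chromosomes],
                "homeolog_group": [c.homeolog_group for c in self.chromosomes],
                "length": [c.length for c in self.chromosomes],
            }
        )
        with open(path, "w") as fh:
            fh.write(f"#bin_size={self.bin_size}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#bin_size="):
                raise ValueError(f"{path}: missing '#bin_size=' header line")
            bin_size = int(header.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        chroms = [
            Chromosome(r.chrom, r.subgenome, int(r.homeolog_group), int(r.length))
            for r in df.itertuples()
        ]
        subs = list(dict.fromkeys(c.subgenome for c in chroms))
        return cls(subs, chroms, bin_size)


def make_layout(
    n_subgenomes: int,
    chroms_per_subgenome: int,
    chrom_length: int,
    bin_size: int,
) -> GenomeLayout:
    """Build a regular polyploid layout.

    Chromosomes are named wheat-style ``{group}{subgenome}`` (1A, 2A, ... 1B,
    ...); the homeolog group is the chromosome's ordinal within its subgenome,
    so group g holds the g-th chromosome of every subgenome.
    """
    for name, v in [
        ("n_subgenomes", n_subgenomes),
        ("chroms_per_subgenome", chroms_per_subgenome),
        ("chrom_length", chrom_length),
        ("bin_size", bin_size),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if n_subgenomes > len(_SUBGENOME_LETTERS):
        raise ValueError(f"at most {len(_SUBGENOME_LETTERS)} subgenomes supported")
    subs = list(_SUBGENOME_LETTERS[:n_subgenomes])
    chroms = [
        Chromosome(f"{g}{s}", s, g, chrom_length)
        for s in subs
        for g in range(1, chroms_per_subgenome + 1)
    ]
    return GenomeLayout(subs, chroms, bin_size)
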