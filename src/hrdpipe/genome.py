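"""Genome geometry: chromosome lengths, centromeres, and arms.

The scar counters only need lengths and centromere intervals, supplied as
a genome-meta TSV (chrom, length, centro_start, centro_end; 1-based
inclusive).  Arms are derived by splitting at the centromere midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class ChromosomeMeta:
    name: str
    length: int
    centro_start: int
    centro_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.centro_start <= self.centro_end <= self.length):
            raise ConfigurationError(
                f"chromosome {self.name}: centromere [{self.centro_start}, "
                f"{self.centro_end}] must lie within [1, {self.length}]"
            )

    @property
    def centromere_mid(self) -> int:
        return (self.centro_start + self.centro_end) // 2


@dataclass(frozen=True)
class GenomeMeta:
    """Ordered chromosome geometry for a (possibly synthetic) genome."""

    chromosomes: tuple[ChromosomeMeta, ...]

    def __getitem__(self, name: str) -> ChromosomeMeta:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ConfigurationError(f"chromosome {name!r} not in genome meta")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "chrom": c.name,
                    "length": c.length,
                    "centro_start": c.centro_start,
                    "centro_end": c.centro_end,
                }
                for c in self.chromosomes
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeMeta":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            tuple(
                ChromosomeMeta(
                    str(r.chrom), int(r.length), int(r.centro_start), int(r.centro_end)
                )
                for r in df.itertuples(index=False)
            )
        )


MB = 1_000_000


def default_synthetic_genome() -> GenomeMeta:
    """Three-chromosome synthetic genome used by the cohort simulator.

    Chromosome sizes span the 150-230 Mb range of large human chromosomes
    with sub-metacentric centromeres, so telomeric/centromeric scar
    geometry (TAI reach, arm splits) is fully exercisable.
    """
    return GenomeMeta(
        (
            ChromosomeMeta("1", 230 * MB, 95 * MB, 100 * MB),
            ChromosomeMeta("2", 180 * MB, 78 * MB, 82 * MB),
            ChromosomeMeta("3", 150 * MB, 58 * MB, 62 * MB),
        )
    )
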