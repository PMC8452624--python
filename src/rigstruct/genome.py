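"""Genome model: chromosome sizes, centromeres (p/q arm split), gene loci."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Tuple

from .model import InputError

__all__ = ["GenomeModel", "GeneLocus", "load_default_genome", "load_default_genes"]


@dataclass(frozen=True)
class GeneLocus:
    symbol: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(f"invalid gene interval for {self.symbol}")


class GenomeModel:
    """Chromosome lengths plus a centromere position defining the p/q arms."""

    def __init__(self, lengths: Dict[str, int], centromeres: Dict[str, int]):
        if set(lengths) != set(centromeres):
            raise InputError("lengths and centromeres must cover the same chromosomes")
        for chrom, length in lengths.items():
            cen = centromeres[chrom]
            if not 0 < cen < length:
                raise InputError(f"{chrom}: centromere {cen} outside (0, {length})")
        self._lengths = dict(lengths)
        self._centromeres = dict(centromeres)

    @property
    def chromosomes(self) -> List[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def length(self, chrom: str) -> int:
        self._check(chrom)
        return self._lengths[chrom]

    def centromere(self, chrom: str) -> int:
        self._check(chrom)
        return self._centromeres[chrom]

    def arm_of(self, chrom: str, pos: int) -> str:
        """Arm label ('p' or 'q') for a 0-based position."""
        return "p" if pos < self.centromere(chrom) else "q"

    def arm_bounds(self, chrom: str, arm: str) -> Tuple[int, int]:
        """0-based half-open bounds of an arm."""
        cen = self.centromere(chrom)
        if arm == "p":
            return 0, cen
        if arm == "q":
            return cen, self.length(chrom)
        raise InputError(f"unknown arm {arm!r}")

    def arm_length(self, chrom: str, arm: str) -> int:
        lo, hi = self.arm_bounds(chrom, arm)
        return hi - lo

    def _check(self, chrom: str) -> None:
        if chrom not in self._lengths:
            raise InputError(f"unknown chromosome {chrom!r}")


def _data_lines(name: str) -> Iterable[str]:
    text = resources.files("rigstruct.data").joinpath(name).read_text()
    return text.splitlines()


def load_default_genome() -> GenomeModel:
    """hg19-like chromosome table packaged with the library."""
    lengths: Dict[str, int] = {}
    centromeres: Dict[str, int] = {}
    lines = iter(_data_lines("genome_hg19.tsv"))
    next(lines)  # header
    for line in lines:
        if not line.strip():
            continue
        chrom, length, cen = line.split("\t")
        lengths[chrom] = int(length)
        centromeres[chrom] = int(cen)
    return GenomeModel(lengths, centromeres)


def load_default_genes() -> List[GeneLocus]:
    """Packaged BED of the recurrently altered genes tracked by the pipeline."""
    genes = []
    for line in _data_lines("genes_hg19.bed"):
        if not line.strip():
            continue
        chrom, start, end, symbol = line.split("\t")
        genes.append(GeneLocus(symbol=symbol, chrom=chrom, start=int(start), end=int(end)))
    return genes
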