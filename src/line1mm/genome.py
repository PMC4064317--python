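"""Genome coordinate model shared by every analysis stage.

All coordinates are 0-based half-open internally.  BED-style inputs pass
through unchanged; published 1-based inclusive tables (e.g. the packaged
common-breakpoint list) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomeManifest",
    "ArmMap",
    "load_cytobands",
    "assign_arm",
    "overlap_bp",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeManifest:
    """Ordered chromosome names, lengths and sex-chromosome flags."""

    lengths: dict[str, int]
    sex_chroms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {n}")
        self.sex_chroms = frozenset(self.sex_chroms)

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in self.sex_chroms]

    def is_sex(self, chrom: str) -> bool:
        return chrom in self.sex_chroms

    @classmethod
    def from_table(cls, path, sex_chroms=("chrX", "chrY", "X", "Y")) -> "GenomeManifest":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
        lengths = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
        return cls(lengths, frozenset(c for c in lengths if c in set(sex_chroms)))

    def to_table(self, path) -> None:
        pd.DataFrame({"chrom": self.chroms, "length": [self.lengths[c] for c in self.chroms]}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class ArmMap:
    """Per-chromosome p/q arm intervals plus the genome manifest.

    Acrocentric chromosomes may carry a single arm; the missing arm is
    simply absent from the mapping.
    """

    arms: dict[str, dict[str, GenomicInterval]]
    manifest: GenomeManifest

    def __post_init__(self) -> None:
        for chrom, by_arm in self.arms.items():
            length = self.manifest.lengths.get(chrom)
            if length is None:
                raise ValueError(f"arm map references unknown chromosome {chrom}")
            spans = sorted(by_arm.items(), key=lambda kv: kv[1].start)
            for _, iv in spans:
                if iv.end > length:
                    raise ValueError(f"arm {iv} exceeds {chrom} length {length}")
            for (_, a), (_, b) in zip(spans, spans[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping arms on {chrom}")

    def arm_interval(self, chrom: str, arm: str) -> GenomicInterval | None:
        return self.arms.get(chrom, {}).get(arm)

    def arm_labels(self) -> list[tuple[str, str]]:
        return [(c, a) for c in self.manifest.chroms for a in sorted(self.arms.get(c, {}))]


def load_cytobands(path, sex_chroms=("chrX", "chrY", "X", "Y")) -> ArmMap:
    """Read a UCSC ``cytoBand.txt``-style file into an :class:`ArmMap`.

    Bands named ``p*`` are merged into the p arm, ``q*`` into the q arm;
    manifest lengths are the maximum band end per chromosome.
    """
    spans: dict[str, dict[str, list[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed cytoband row at line {lineno}: {line!r}")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer coordinate at line {lineno}") from exc
            arm = name[:1]
            if arm not in ("p", "q"):
                raise ValueError(f"{path}: band name {name!r} at line {lineno} has no p/q prefix")
            lo_hi = spans.setdefault(chrom, {}).setdefault(arm, [start_i, end_i])
            lo_hi[0] = min(lo_hi[0], start_i)
            lo_hi[1] = max(lo_hi[1], end_i)
    lengths = {c: max(hi for _, hi in by_arm.values()) for c, by_arm in spans.items()}
    manifest = GenomeManifest(lengths, frozenset(c for c in lengths if c in set(sex_chroms)))
    arms = {
        c: {arm: GenomicInterval(c, lo, hi) for arm, (lo, hi) in by_arm.items()}
        for c, by_arm in spans.items()
    }
    return ArmMap(arms, manifest)


def assign_arm(iv: GenomicInterval, arms: ArmMap) -> str:
    """Arm label (``"p"`` or ``"q"``) containing the interval midpoint."""
    by_arm = arms.arms.get(iv.chrom)
    if not by_arm:
        raise KeyError(f"chromosome {iv.chrom} absent from arm map")
    mid = iv.midpoint
    for label, span in by_arm.items():
        if span.start <= mid < span.end:
            return label
    raise ValueError(f"midpoint {mid} of {iv} falls outside every arm of {iv.chrom}")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))
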