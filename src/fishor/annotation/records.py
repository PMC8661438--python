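"""Result records for mined loci and per-species repertoires."""

from __future__ import annotations

from dataclasses import dataclass, field

CLASSES = ("functional", "pseudogene", "truncated", "edge")


@dataclass
class ORGeneRecord:
    """One mined locus (0-based half-open forward-strand coordinates)."""

    id: str
    scaffold: str
    start: int
    end: int
    strand: str
    cls: str
    family: str | None
    seq: str
    evidence: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ORRepertoire:
    """All mined loci of one species with class and family tallies."""

    species_id: str
    records: list[ORGeneRecord] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for rec in self.records:
            counts[rec.cls] += 1
        return counts

    @property
    def family_counts(self) -> dict[str, int]:
        """Family tallies among functional genes."""
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.cls == "functional":
                counts[rec.family or "unclassified"] = \
                    counts.get(rec.family or "unclassified", 0) + 1
        return counts

    @property
    def n_functional(self) -> int:
        return self.class_counts["functional"]

    def of_class(self, cls: str) -> list[ORGeneRecord]:
        return [r for r in self.records if r.cls == cls]
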