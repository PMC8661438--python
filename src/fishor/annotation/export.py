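"""Repertoire export: GFF3, per-class FASTA, summary rows."""

from __future__ import annotations

from fishor.annotation.records import CLASSES, ORRepertoire


def repertoire_to_gff3(rep: ORRepertoire) -> str:
    """GFF3 rendering (1-based inclusive coordinates on output)."""
    lines = ["##gff-version 3"]
    for rec in rep.records:
        attrs = f"ID={rec.id};class={rec.cls}"
        if rec.family:
            attrs += f";family={rec.family}"
        lines.append("\t".join([
            rec.scaffold, "fishor", "gene", str(rec.start + 1), str(rec.end),
            ".", rec.strand, ".", attrs]))
    return "\n".join(lines) + "\n"


def repertoire_summary_row(rep: ORRepertoire, families=None) -> dict:
    """One summary row: per-class counts plus per-family functional counts."""
    row: dict = {"species": rep.species_id}
    counts = rep.class_counts
    for cls in CLASSES:
        row[f"n_{cls}"] = counts[cls]
    fam_counts = rep.family_counts
    for fam in sorted(set(fam_counts) | set(families or [])):
        row[f"fam_{fam}"] = fam_counts.get(fam, 0)
    return row


def class_fasta(rep: ORRepertoire, cls: str, width: int = 80) -> str:
    out = []
    for rec in rep.of_class(cls):
        out.append(f">{rec.id} {rec.scaffold}:{rec.start}-{rec.end}({rec.strand})")
        for i in range(0, len(rec.seq), width):
            out.append(rec.seq[i:i + width])
    return "\n".join(out) + ("\n" if out else "")
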