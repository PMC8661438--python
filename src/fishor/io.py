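"""Plain-text writers for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

from fishor.synth.genome import SyntheticGenome


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path, width: int = 80):
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_genome(genome: SyntheticGenome, fasta_path, truth_path):
    """Genome FASTA plus the truth table TSV (0-based half-open)."""
    write_fasta(genome.scaffolds, fasta_path)
    with open(truth_path, "w") as fh:
        fh.write("scaffold\tstart\tend\tstrand\tclass\tfamily\tsource_id\n")
        for loc in genome.truth:
            fh.write(f"{loc.scaffold}\t{loc.start}\t{loc.end}\t{loc.strand}\t"
                     f"{loc.cls}\t{loc.family}\t{loc.source_id}\n")


def write_traits_tsv(traits: dict[str, dict], path):
    """``traits`` maps column name -> {species -> value}."""
    cols = sorted(traits)
    species = sorted({s for col in traits.values() for s in col})
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(cols) + "\n")
        for sp in species:
            vals = [str(traits[c].get(sp, "NA")) for c in cols]
            fh.write(sp + "\t" + "\t".join(vals) + "\n")


def read_traits_tsv(path) -> dict[str, dict]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    key = df.columns[0]
    out = {}
    for col in df.columns[1:]:
        out[col] = {str(r[key]): r[col] for _, r in df.iterrows()
                    if str(r[col]) not in ("NA", "nan")}
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
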