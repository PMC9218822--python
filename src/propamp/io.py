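"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; gene tables and annotations as GFF3 (1-based
inclusive on disk, converted to the package's 0-based half-open
coordinates at this boundary and nowhere else); matches and fragments as
BED (0-based half-open, like the internal convention); tabular summaries
as TSV; truth and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from propamp.assembly import PropellerAnnotation
from propamp.profiles import BladeMatch
from propamp.simulate import GeneRecord, Genome, TruthRecord

GFF_SOURCE = "propamp"


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# GFF3 gene tables (flat CDS features)


def write_gene_table(genome: Genome, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genome.genes:
        lines.append("\t".join([
            genome.genome_id, GFF_SOURCE, "CDS", str(g.start + 1),
            str(g.end), ".", g.strand, "0", f"ID={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_table(path: str | Path) -> tuple[str, list[GeneRecord]]:
    genome_id = ""
    genes: list[GeneRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "CDS":
            continue
        genome_id = fields[0]
        attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if kv)
        genes.append(GeneRecord(attrs.get("ID", f"gene{len(genes)}"),
                                int(fields[3]) - 1, int(fields[4]),
                                fields[6]))
    genes.sort(key=lambda g: g.start)
    return genome_id, genes


# --------------------------------------------------------------------------
# propeller annotations


def write_propellers_gff3(propellers: list[PropellerAnnotation],
                          path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for k, p in enumerate(propellers):
        pid = f"propeller{k}"
        attrs = (f"ID={pid};n_blades={p.n_blades};"
                 f"median_identity={p.median_blade_identity:.4f};"
                 f"family={p.family};locality={p.locality}")
        lines.append("\t".join([
            p.protein_id, GFF_SOURCE, "propeller", str(p.start + 1),
            str(p.end), ".", "+", ".", attrs]))
        for b, (s, e) in enumerate(p.blade_intervals):
            lines.append("\t".join([
                p.protein_id, GFF_SOURCE, "blade", str(s + 1), str(e),
                ".", "+", ".", f"ID={pid}.b{b};Parent={pid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def propellers_to_frame(propellers: list[PropellerAnnotation]
                        ) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein_id": p.protein_id, "start": p.start, "end": p.end,
        "n_blades": p.n_blades,
        "median_identity": round(p.median_blade_identity, 4),
        "family": p.family, "locality": p.locality,
        "min_terminus_distance": p.min_terminus_distance,
    } for p in propellers])


# --------------------------------------------------------------------------
# matches


def matches_to_frame(matches: list[BladeMatch]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein_id": m.protein_id, "start": m.start, "end": m.end,
        "score": round(m.score, 3), "p": m.significance,
        "coverage": round(m.query_coverage, 4),
    } for m in matches])


def write_matches_bed(matches: list[BladeMatch], path: str | Path) -> None:
    lines = ["\t".join([m.protein_id, str(m.start), str(m.end),
                        f"blade_p{m.significance:.4g}", f"{m.score:.1f}",
                        "+"])
             for m in matches]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_fragments_bed(fragments, path: str | Path) -> None:
    lines = ["\t".join([f.genome_id, str(f.nt_start), str(f.nt_end),
                        f"frag_f{f.frame}", f"{f.confidence:.4f}", "+"])
             for f in fragments]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------------------
# truth


def write_truth(truths: dict[str, TruthRecord], path: str | Path) -> None:
    payload = {k: truths[k].to_dict() for k in sorted(truths)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True)
                          + "\n")


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    payload = json.loads(Path(path).read_text())
    return {k: TruthRecord.from_dict(v) for k, v in payload.items()}


def write_genome(genome: Genome, outdir: str | Path,
                 prefix: str = "genome") -> dict[str, Path]:
    """Emit genome FASTA, GFF3 gene table, protein FASTA, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / f"{prefix}.fna",
        "genes": outdir / f"{prefix}.gff3",
        "proteins": outdir / f"{prefix}.faa",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_fasta({genome.genome_id: genome.sequence}, paths["genome"])
    write_gene_table(genome, paths["genes"])
    write_fasta({g.gene_id: genome.protein_of(g.gene_id)
                 for g in genome.genes}, paths["proteins"])
    write_truth(genome.truths, paths["truth"])
    return paths
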