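"""Readers and writers for the tabular and sequence formats of the pipeline.

All tabular I/O is header-carrying TSV with 0-based ranks and opaque gene
identifiers.  Identity columns and STRING-style combined scores are
autodetected as percent/0-1000 scales and normalised to [0, 1].  Codon
pairs travel as paired FASTA (``gene|focal`` / ``gene|relative`` records),
ontologies as an OBO subset (id, name, def, is_a) or an equivalent TSV,
and trees as Newick.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phylostress.divergence import CodonPairAlignment
from phylostress.gene_sets import AnnotationRecord, OntologyTerm
from phylostress.taxonomy import Lineage, Phylostratum


# ---------------------------------------------------------------- lineage

def read_lineage(lineage_path, species_path, focal_species: str) -> Lineage:
    """Lineage from a rank/name TSV plus a species assignment TSV."""
    strata_df = pd.read_csv(lineage_path, sep="\t")
    species_df = pd.read_csv(species_path, sep="\t")
    by_stratum = species_df.groupby("stratum_name")["species_id"].agg(set)
    strata = []
    for _, row in strata_df.sort_values("rank").iterrows():
        species = by_stratum.get(row["name"], set())
        strata.append(Phylostratum(row["name"], int(row["rank"]), frozenset(species)))
    return Lineage(tuple(strata), focal_species)


def write_lineage(lineage: Lineage, lineage_path, species_path) -> None:
    pd.DataFrame(
        {"rank": lineage.ranks, "name": lineage.names}
    ).to_csv(lineage_path, sep="\t", index=False)
    rows = [
        (sp, s.name)
        for s in lineage.strata
        for sp in sorted(s.species)
    ]
    pd.DataFrame(rows, columns=["species_id", "stratum_name"]).to_csv(
        species_path, sep="\t", index=False
    )


# ------------------------------------------------------------------- hits

def read_ortholog_hits(path) -> pd.DataFrame:
    """Hit table gene_id/species_id/identity; percent scale autodetected."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species_id", "identity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) and df["identity"].max() > 1.5:
        df["identity"] = df["identity"] / 100.0
    return df


def write_gene_ages(ages: pd.DataFrame, path) -> None:
    ages[["gene_id", "pai"]].to_csv(path, sep="\t", index=False)


def read_gene_ages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------ edges

def read_edges(path):
    """STRING-style edge TSV; 0-1000 combined scores autodetected."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_a", "protein_b", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    scores = df["combined_score"].astype(float)
    if len(scores) and scores.max() > 1.5:
        scores = scores / 1000.0
    return list(zip(df["protein_a"], df["protein_b"], scores))


def write_edges(edges, path) -> None:
    pd.DataFrame(edges, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_clusters(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["node"], df["label"]))


# ------------------------------------------------------------ codon pairs

def write_codon_pairs(alignments, path) -> None:
    records = []
    for aln in alignments:
        records.append(SeqRecord(Seq(aln.seq_focal), id=f"{aln.gene}|focal", description=""))
        records.append(
            SeqRecord(Seq(aln.seq_relative), id=f"{aln.gene}|relative", description="")
        )
    SeqIO.write(records, path, "fasta")


def read_codon_pairs(path):
    """Paired FASTA -> list of CodonPairAlignment (gene|focal, gene|relative)."""
    focal, relative = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, role = rec.id.partition("|")
        if role == "focal":
            focal[gene] = str(rec.seq)
        elif role == "relative":
            relative[gene] = str(rec.seq)
        else:
            raise ValueError(f"{path}: record {rec.id!r} lacks a |focal / |relative role")
    odd = set(focal) ^ set(relative)
    if odd:
        raise ValueError(f"{path}: unpaired gene record(s) {sorted(odd)[:5]}")
    return [
        CodonPairAlignment(gene=g, seq_focal=focal[g], seq_relative=relative[g])
        for g in sorted(focal)
    ]


def write_divergence_results(results, path) -> None:
    pd.DataFrame(
        [(r.gene, r.ka, r.ks, r.di, r.status) for r in results],
        columns=["gene_id", "ka", "ks", "di", "status"],
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- ontology

def write_ontology_obo(terms, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(terms, key=lambda t: t.id):
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.id}\n")
            fh.write(f"name: {t.name}\n")
            if t.definition:
                fh.write(f'def: "{t.definition}" []\n')
            for p in sorted(t.parents):
                fh.write(f"is_a: {p}\n")


def read_ontology_obo(path):
    """OBO subset reader (id, name, def, is_a) -> list of OntologyTerm."""
    terms = []
    current = None

    def flush():
        if current and "id" in current:
            terms.append(
                OntologyTerm(
                    id=current["id"],
                    name=current.get("name", ""),
                    definition=current.get("def", ""),
                    parents=frozenset(current.get("is_a", ())),
                )
            )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                flush()
                current = {}
            elif current is not None and ": " in line:
                key, _, value = line.partition(": ")
                if key == "is_a":
                    current.setdefault("is_a", []).append(value.split(" ! ")[0].strip())
                elif key == "def":
                    current["def"] = value.split('" [')[0].strip('"')
                elif key in ("id", "name"):
                    current[key] = value.strip()
    flush()
    return terms


def write_annotations(annotations, path) -> None:
    pd.DataFrame(
        [(a.gene, a.term, a.evidence) for a in annotations],
        columns=["gene_id", "term_id", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path):
    df = pd.read_csv(path, sep="\t")
    return [
        AnnotationRecord(gene=row.gene_id, term=row.term_id, evidence=row.evidence)
        for row in df.itertuples()
    ]


# -------------------------------------------------------------- gene sets

def write_gene_set(gene_set, path) -> None:
    pd.DataFrame({"gene_id": sorted(gene_set.genes)}).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list:
    return pd.read_csv(path, sep="\t")["gene_id"].tolist()


# ----------------------------------------------------------------- report

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(value):
    import numpy as np

    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    raise TypeError(f"cannot serialise {type(value)!r}")
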