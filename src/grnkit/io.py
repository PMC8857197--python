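"""File I/O for networks, gene tables, sequences, motifs, and rankings.

All tabular formats are plain UTF-8 TSV with a ``#``-prefixed header line.
Interaction files carry ``regulator target effect evidence experiments
sources`` with semicolon-delimited multi-value fields; gene tables use
1-based inclusive coordinates with strand ``+``/``-``.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .core import (
    Effect,
    EvidenceLevel,
    ExperimentCatalog,
    GRN,
    GRNError,
    Gene,
    RegulatoryInteraction,
)

INTERACTION_COLUMNS = [
    "regulator",
    "target",
    "effect",
    "evidence",
    "experiments",
    "sources",
]

GENE_TABLE_COLUMNS = ["locus_tag", "replicon", "start", "end", "strand"]


def _split_multi(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell or cell == ".":
        return frozenset()
    return frozenset(p.strip() for p in cell.split(";") if p.strip())


def read_interactions_tsv(path: str | os.PathLike, label: str | None = None) -> GRN:
    """Read an interaction TSV into a :class:`GRN`."""
    net = GRN(label=label if label is not None else os.path.basename(str(path)))
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GRNError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            parts += [""] * (6 - len(parts))
            reg, tgt, effect, evidence, experiments, sources = parts[:6]
            net.add_interaction(
                RegulatoryInteraction(
                    regulator=reg,
                    target=tgt,
                    effect=Effect.parse(effect) if effect else Effect.UNKNOWN,
                    evidence=EvidenceLevel.parse(evidence)
                    if evidence
                    else EvidenceLevel.WEAK,
                    experiments=_split_multi(experiments),
                    sources=_split_multi(sources),
                )
            )
    return net


def write_interactions_tsv(network: GRN, path: str | os.PathLike) -> None:
    """Write a :class:`GRN` as interaction TSV (sorted, reproducible)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(INTERACTION_COLUMNS) + "\n")
        for key in sorted(network.interactions):
            inter = network.interactions[key]
            handle.write(
                "\t".join(
                    [
                        inter.regulator,
                        inter.target,
                        inter.effect.value,
                        str(inter.evidence),
                        ";".join(sorted(inter.experiments)),
                        ";".join(sorted(inter.sources)),
                    ]
                )
                + "\n"
            )


def read_gene_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene coordinate table (locus_tag, replicon, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, header=None,
                     names=GENE_TABLE_COLUMNS, skip_blank_lines=True)
    if df.iloc[0, 0].startswith("#"):
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise GRNError(
            "unknown strand for genes: "
            + ", ".join(df.loc[bad, "locus_tag"].tolist()[:10])
        )
    if (df["start"] > df["end"]).any():
        raise GRNError("gene table rows must satisfy start <= end (1-based inclusive)")
    return df


def write_gene_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(GENE_TABLE_COLUMNS) + "\n")
        df.to_csv(handle, sep="\t", header=False, index=False,
                  columns=GENE_TABLE_COLUMNS)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into a dict of upper-case sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_catalog(path: str | os.PathLike) -> ExperimentCatalog:
    """Load an experiment->evidence catalog from YAML ({name: strong|weak})."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    catalog = ExperimentCatalog({})
    for name, level in raw.items():
        catalog.add(str(name), EvidenceLevel.parse(str(level)))
    return catalog


def write_catalog(catalog: ExperimentCatalog, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(
            {name: str(level) for name, level in sorted(catalog.items())},
            handle,
            sort_keys=True,
        )


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Genes x conditions expression TSV (first column gene ids, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise GRNError("expression matrix contains missing values")
    if df.shape[1] < 2:
        raise GRNError("expression matrix needs >= 2 conditions")
    if df.index.duplicated().any():
        raise GRNError("duplicate gene ids in expression matrix")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t")


def read_ortholog_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV of strictly 1:1 ortholog pairs (organism A -> B)."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            pairs.append((a, b))
    return validate_one_to_one(pairs)


def validate_one_to_one(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    seen_b: dict[str, str] = {}
    offenders: list[str] = []
    for a, b in pairs:
        if a in mapping and mapping[a] != b:
            offenders.append(a)
        if b in seen_b and seen_b[b] != a:
            offenders.append(b)
        mapping[a] = b
        seen_b[b] = a
    if offenders:
        raise GRNError(
            "ortholog map is not one-to-one; offending ids: "
            + ", ".join(sorted(set(offenders))[:20])
        )
    return mapping


def write_ortholog_map(mapping: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#gene_a\tgene_b\n")
        for a in sorted(mapping):
            handle.write(f"{a}\t{mapping[a]}\n")


# -- MEME minimal motif format -------------------------------------------


def write_meme_motifs(pwms, path: str | os.PathLike) -> None:
    """Write PWMs in MEME minimal motif format."""
    import numpy as np

    with open(path, "w", encoding="utf-8") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = np.asarray(pwms[0].background, dtype=float)
        handle.write("Background letter frequencies\n")
        handle.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg)
        )
        for pwm in pwms:
            handle.write(f"MOTIF {pwm.tf}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {pwm.source_sites} E= 0\n"
            )
            for row in pwm.matrix:
                handle.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            handle.write("\n")


def read_meme_motifs(path: str | os.PathLike):
    """Read PWMs from MEME minimal motif format."""
    import numpy as np

    from .motifs import PWM

    pwms = []
    background = np.full(4, 0.25)
    with open(path, encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            background = np.array(
                [float(fields[j]) for j in (1, 3, 5, 7)], dtype=float
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            tf = line.split()[1]
            i += 1
            while not lines[i].startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            nsites = 3
            if "nsites=" in header:
                nsites = int(float(header.split("nsites=")[1].split()[0]))
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            matrix = np.array(rows, dtype=float)
            matrix /= matrix.sum(axis=1, keepdims=True)  # fixed-precision rows
            pwms.append(
                PWM(
                    tf=tf,
                    matrix=matrix,
                    background=background.copy(),
                    source_sites=max(nsites, 3),
                )
            )
            i += 1 + width
            continue
        i += 1
    return pwms
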