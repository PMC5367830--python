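"""File formats: FASTA datasets, PWM (JASPAR PFM / MEME minimal), gPOIM TSV.

All positions in files and logs are 1-based inclusive.  TSV is the
canonical importance-matrix interchange format so artifacts stay diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._kmers import ALPHABET, index_to_kmer, kmer_index
from .gpoim import GPoim
from .motif_extraction import Ppm
from .simulate import MotifSpec, SequenceDataset


# ---------------------------------------------------------------- FASTA


def write_fasta(data: SequenceDataset, path, manifest: bool = True) -> None:
    """Write a dataset as FASTA with ``label=+/-1`` in the description lines.

    A sidecar ``<path>.manifest.json`` records n, L, planted motifs,
    fractions, mutation rate, and seed.
    """
    path = Path(path)
    records = []
    for i, (seq, label) in enumerate(zip(data.sequences, data.labels)):
        records.append(
            SeqRecord(Seq(seq), id=f"seq{i + 1}", description=f"label={label:+d}")
        )
    SeqIO.write(records, str(path), "fasta")
    if manifest:
        meta = {
            "n": len(data),
            "L": data.L,
            "positive_fraction": data.positive_fraction,
            "mutation_rate": data.mutation_rate,
            "seed": data.seed,
            "motifs": [
                {
                    "pattern": m.pattern if not m.is_pwm else m.pattern.tolist(),
                    "position": m.position,
                    "name": m.name,
                }
                for m in data.planted
            ],
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(meta, indent=2)
        )


def read_fasta(path) -> SequenceDataset:
    """Read a FASTA dataset; labels parsed from ``label=+/-1`` descriptions.

    Sequences are uppercased and validated (strict ACGT, uniform length).
    Records without a label parse as unlabeled only if none carry one;
    mixed labeling is rejected.
    """
    path = Path(path)
    seqs, labels, ids = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGT characters {sorted(bad)}"
            )
        seqs.append(seq)
        ids.append(rec.id)
        label = None
        for token in rec.description.split():
            if token.startswith("label="):
                label = int(token.split("=", 1)[1])
        labels.append(label)
    if not seqs:
        raise ValueError(f"no records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        offending = [i for i, s in zip(ids, seqs) if len(s) != len(seqs[0])]
        raise ValueError(f"ragged sequence lengths; offending records: {offending}")
    if any(l is None for l in labels):
        if any(l is not None for l in labels):
            raise ValueError("mixed labeled and unlabeled records")
        labels = [1] * len(seqs)  # unlabeled fallback
    planted = []
    manifest = path.with_suffix(path.suffix + ".manifest.json")
    meta = {}
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        for m in meta.get("motifs", []):
            pattern = m["pattern"]
            if isinstance(pattern, list):
                pattern = np.asarray(pattern)
            planted.append(MotifSpec(pattern, m["position"], m.get("name", "")))
    return SequenceDataset(
        seqs,
        np.asarray(labels),
        len(seqs[0]),
        planted=planted,
        positive_fraction=meta.get(
            "positive_fraction", float(np.mean(np.asarray(labels) == 1))
        ),
        mutation_rate=meta.get("mutation_rate", 0.0),
        seed=meta.get("seed", 0),
    )


# ---------------------------------------------------------------- PWM formats


def write_pwm(p: Ppm, path, format: str = "jaspar", name: "str | None" = None) -> None:
    """Write a PWM as JASPAR PFM (counts = round(1000 * r)) or MEME minimal."""
    path = Path(path)
    name = name or p.name or "motif"
    if format == "jaspar":
        counts = np.round(1000 * p.r).astype(int)
        lines = [f">{name} mu={p.mu}"]
        for row, base in zip(counts, ALPHABET):
            lines.append(f"{base} [ " + " ".join(str(v) for v in row) + " ]")
        path.write_text("\n".join(lines) + "\n")
    elif format == "meme":
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {p.k} nsites= 1000 E= 0",
        ]
        for col in p.r.T:
            lines.append(" " + " ".join(f"{v:.6f}" for v in col))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("format must be 'jaspar' or 'meme'")


def read_pwm(path, format: str = "jaspar") -> Ppm:
    """Read a PWM written by :func:`write_pwm`; columns are renormalized."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if format == "jaspar":
        header = text[0]
        mu = 1
        for token in header.split():
            if token.startswith("mu="):
                mu = int(token.split("=")[1])
        rows = []
        for line in text[1:5]:
            inner = line.split("[", 1)[1].rsplit("]", 1)[0]
            rows.append([float(v) for v in inner.split()])
        r = np.asarray(rows)
        r = r / r.sum(axis=0)
        return Ppm(r, mu, name=header[1:].split()[0])
    if format == "meme":
        name = "motif"
        cols = []
        in_matrix = False
        for line in text:
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line.strip():
                cols.append([float(v) for v in line.split()])
        r = np.asarray(cols).T
        r = r / r.sum(axis=0)
        return Ppm(r, 1, name=name)
    raise ValueError("format must be 'jaspar' or 'meme'")


# ---------------------------------------------------------------- gPOIM TSV


def write_gpoim_tsv(g: GPoim, path) -> None:
    """TSV with columns (k, position, kmer, value, count) + JSON header line."""
    path = Path(path)
    header = {
        "k": g.k,
        "L": g.L,
        "n_samples": g.n_samples,
        "centered": g.centered,
        "seed": g.seed,
        "scorer_name": g.scorer_name,
        "mean_score": g.mean_score,
    }
    rows = []
    counts = g.counts
    for y in range(4**g.k):
        kmer = index_to_kmer(y, g.k)
        for j in range(g.n_positions):
            v = g.values[y, j]
            c = int(counts[y, j]) if counts is not None else -1
            if counts is not None and c == 0:
                continue  # empty bins propagate as missing rows
            rows.append((g.k, j + 1, kmer, v, c))
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("k\tposition\tkmer\tvalue\tcount\n")
        for row in rows:
            fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]:.12g}\t{row[4]}\n")


def read_gpoim_tsv(path) -> GPoim:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON metadata header")
        header = json.loads(first[2:])
        df = pd.read_csv(fh, sep="\t")
    k, L = header["k"], header["L"]
    values = np.full((4**k, L - k + 1), np.nan)
    exact = bool((df["count"] == -1).all()) if len(df) else False
    counts = None if exact else np.zeros((4**k, L - k + 1), dtype=np.int64)
    for _, row in df.iterrows():
        y = kmer_index(row["kmer"])
        j = int(row["position"]) - 1
        values[y, j] = row["value"]
        if counts is not None:
            counts[y, j] = int(row["count"])
    return GPoim(
        k=k, L=L, values=values, counts=counts,
        n_samples=header.get("n_samples", 0),
        centered=header.get("centered", True),
        seed=header.get("seed"),
        scorer_name=header.get("scorer_name", ""),
        mean_score=header.get("mean_score", 0.0),
    )


def write_diffpoim_tsv(d, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("l\tj\tomega\n")
        for l in range(1, d.k_max + 1):
            for j in range(1, d.L - l + 2):
                fh.write(f"{l}\t{j}\t{d.omega[l - 1, j - 1]:.12g}\n")
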