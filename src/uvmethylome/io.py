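"""Readers and writers for the plain-text formats the pipeline exchanges.

All coordinates are converted to the package-internal 0-based half-open
convention on read: methratio-style tables and GFF3 are 1-based inclusive on
disk, BED is already 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeAnnotation, GenomeSequence, GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff3_features",
    "read_chromatin_states_bed",
    "read_methratio",
    "write_methratio",
    "read_cx_report",
    "read_read_intervals",
    "write_image",
    "read_image",
]

#: methratio-style column order: chrom, 1-based pos, strand, context, ratio,
#: methylated count, total count
METHRATIO_COLUMNS = {
    "chrom": 0,
    "pos": 1,
    "strand": 2,
    "context": 3,
    "ratio": 4,
    "n_meth": 5,
    "n_total": 6,
}


def read_fasta(path: str | Path) -> GenomeSequence:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """3-column or BED6 reader (name/score/strand optional)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_gff3_features(path: str | Path) -> list[GenomicInterval]:
    """GFF3 feature reader: transposable_element → TE (family from the
    ``family=`` attribute when present), gene → PCG."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("transposable_element", "transposon"):
                family = attrd.get("family", "")
                name = f"TE:{family}" if family else "TE"
            elif ftype in ("gene", "protein_coding_gene"):
                name = "PCG"
            else:
                continue
            out.append(
                GenomicInterval(chrom, int(start) - 1, int(end), strand, name)
            )
    return out


def read_chromatin_states_bed(path: str | Path) -> list[GenomicInterval]:
    """Chromatin states as BED with the state integer (1–9) in the name
    column."""
    states = read_bed(path)
    for iv in states:
        if iv.name not in {str(i) for i in range(1, 10)}:
            raise ValueError(f"invalid chromatin state {iv.name!r}")
    return states


def read_methratio(
    path: str | Path, columns: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Per-cytosine call table in the methratio dialect (1-based positions on
    disk → 0-based in memory)."""
    cols = dict(METHRATIO_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "chrom": df[cols["chrom"]].astype(str),
            "pos": df[cols["pos"]].astype(int) - 1,
            "strand": df[cols["strand"]].astype(str),
            "context": df[cols["context"]].astype(str),
            "n_meth": df[cols["n_meth"]].astype(int),
            "n_total": df[cols["n_total"]].astype(int),
        }
    )
    if (out["n_meth"] > out["n_total"]).any():
        raise ValueError("methylated count exceeds total count")
    return out


def write_methratio(calls: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "pos": calls["pos"] + 1,
            "strand": calls["strand"],
            "context": calls["context"],
            "ratio": (calls["n_meth"] / calls["n_total"]).round(4),
            "n_meth": calls["n_meth"],
            "n_total": calls["n_total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Bismark cytosine (CX) report: chrom, 1-based pos, strand, methylated
    count, unmethylated count, context, trinucleotide.  Uncovered positions
    (total 0) are dropped."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"],
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(int) - 1,
            "strand": df["strand"].astype(str),
            "context": df["context"].astype(str),
            "n_meth": df["n_meth"].astype(int),
            "n_total": (df["n_meth"] + df["n_unmeth"]).astype(int),
        }
    )
    return out[out["n_total"] > 0].reset_index(drop=True)


def read_read_intervals(path: str | Path) -> pd.DataFrame:
    """Aligned-read intervals as BED (first 3 columns used) or a plain
    chrom/start/end TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
        }
    )


def write_read_intervals(reads: pd.DataFrame, path: str | Path) -> None:
    reads[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0,1] as 16-bit TIFF or PNG by extension."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(str(path), (arr * 65535).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)), dtype=float)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, GenomicInterval):
            return {"chrom": o.chrom, "start": o.start, "end": o.end,
                    "strand": o.strand, "name": o.name}
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def annotation_to_files(
    annotation: GenomeAnnotation, outdir: str | Path
) -> dict[str, Path]:
    """Write pericentromeres, features and chromatin states as BED files."""
    outdir = Path(outdir)
    paths = {
        "pericentromeres": outdir / "pericentromeres.bed",
        "features": outdir / "features.bed",
        "chromatin_states": outdir / "chromatin_states.bed",
    }
    write_bed(annotation.pericentromeres, paths["pericentromeres"])
    write_bed(annotation.features, paths["features"])
    write_bed(annotation.chromatin_states, paths["chromatin_states"])
    return paths
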