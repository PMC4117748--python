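"""Region handling and file formats.

Regions are 0-based half-open internally; every emitted TSV/VCF position is
1-based.  BED input is padded (10 flanking positions by default, matching
exon-capture practice), sorted and merged before use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "RegionSet",
    "load_regions",
    "write_calls",
    "read_calls",
    "write_vcf",
    "load_allele_map",
    "write_allele_map",
    "write_run_metadata",
]


@dataclass
class RegionSet:
    """Sorted, merged, non-overlapping genomic intervals."""

    intervals: list = field(default_factory=list)  # (contig, start, end)
    padding: int = 0

    def __post_init__(self) -> None:
        self.intervals = self._normalize(self.intervals)

    @staticmethod
    def _normalize(intervals):
        merged = []
        for contig, start, end in sorted(intervals):
            if merged and merged[-1][0] == contig and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (contig, prev[1], max(prev[2], end))
            else:
                merged.append((contig, max(0, start), end))
        return merged

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)

    @property
    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def load_regions(path, padding: int = 10) -> RegionSet:
    """Read a BED-like file (>= 3 columns, 0-based half-open), pad each
    interval symmetrically, and normalize.  Malformed lines raise with their
    line number; an empty file yields an empty set."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                contig = parts[0]
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            intervals.append((contig, max(0, start - padding), end + padding))
    return RegionSet(intervals=intervals, padding=padding)


# ---------------------------------------------------------------------------
# call tables

_NA_TOKEN = "NA"


def write_calls(table: pd.DataFrame, path) -> None:
    """Tab-separated call table, one row per gated site; 1-based positions,
    NA for missing values.  Round-trips losslessly through
    :func:`read_calls`."""
    out = table.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, na_rep=_NA_TOKEN, float_format="%.17g")


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=[_NA_TOKEN],
        keep_default_na=False,
        dtype={"contig": str, "filters": str},
    )
    df["pos"] = df["pos"] - 1
    df["filters"] = df["filters"].fillna("")
    for col in ("major_dna", "major_rna"):
        df[col] = df[col].where(df[col].notna(), None)
    for col in ("sig_dna", "sig_meta"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower() == "true"
    return df


def _vcf_ref_alt(row, reference):
    """VCF (1-based pos, REF, ALT) for the site's DNA-major (or RNA-major)
    variant allele."""
    allele = row["major_dna"] or row["major_rna"]
    contig, pos = row["contig"], int(row["pos"])
    if allele is None:
        return None
    if allele.startswith("+"):  # insertion anchored at pos
        anchor = reference.fetch(contig, pos, pos + 1).upper()
        return pos + 1, anchor, anchor + allele[1:]
    if allele.startswith("-"):  # deletion of L bases starting at pos
        length = int(allele[1:])
        anchor = reference.fetch(contig, pos - 1, pos + length).upper()
        return pos, anchor, anchor[0]
    ref = reference.fetch(contig, pos, pos + 1).upper()
    return pos + 1, ref, allele


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=P_DNA,Number=1,Type=Float,Description="DNA beta-binomial tail P-value">
##INFO=<ID=P_RNA,Number=1,Type=Float,Description="RNA beta-binomial tail P-value">
##INFO=<ID=P_META,Number=1,Type=Float,Description="Stouffer-combined DNA+RNA P-value">
##INFO=<ID=MAF_DNA,Number=1,Type=Float,Description="DNA mutant allele fraction k/n">
##INFO=<ID=MAF_RNA,Number=1,Type=Float,Description="RNA mutant allele fraction k/n">
##FILTER=<ID=strand_bias,Description="Variant vs germline strand chi-square P < 0.01">
##FILTER=<ID=indel_strand,Description="Indel variant lacking reads on both strands">
##FILTER=<ID=prevalence,Description="Major variant below 75% of variant reads">
##FILTER=<ID=end_distance_mad,Description="MAD of variant read end distances < 1">
"""


def write_vcf(table: pd.DataFrame, path, reference) -> None:
    """VCF 4.2 of variant-bearing sites (k >= 1 in either modality).

    INFO carries the per-model P-values and MAFs; FILTER lists the failed
    variant-filter clauses (the modality prefix dropped), PASS otherwise.
    Simulator spike alleles use the non-nucleotide base V, which is written
    verbatim.
    """
    close = False
    if not isinstance(reference, pysam.FastaFile):
        reference = pysam.FastaFile(str(reference))
        close = True
    try:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for contig, length in zip(reference.references, reference.lengths):
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            sub = table[(table["k_dna"] > 0) | (table["k_rna"] > 0)]
            for _, row in sub.iterrows():
                spot = _vcf_ref_alt(row, reference)
                if spot is None:
                    continue
                pos1, ref, alt = spot
                flags = sorted(
                    {f.split(":", 1)[-1] for f in row["filters"].split(",") if f}
                )
                filt = ";".join(flags) if flags else "PASS"
                info = []
                for key, val in (
                    ("P_DNA", row["p_dna"]),
                    ("P_RNA", row["p_rna"]),
                    ("P_META", row["p_meta"]),
                    ("MAF_DNA", row["maf_dna"]),
                    ("MAF_RNA", row["maf_rna"]),
                ):
                    if not (isinstance(val, float) and np.isnan(val)):
                        info.append(f"{key}={val:.6g}")
                fh.write(
                    f"{row['contig']}\t{pos1}\t.\t{ref}\t{alt}\t.\t{filt}\t"
                    + (";".join(info) or ".")
                    + "\n"
                )
    finally:
        if close:
            reference.close()


# ---------------------------------------------------------------------------
# polymorphism / artifact allele maps


def _alt_to_allele(ref: str, alt: str, pos0: int):
    """Convert a VCF REF/ALT pair to the internal (position, allele) form."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return pos0, alt
    if len(alt) > len(ref) and alt.startswith(ref):
        return pos0 + len(ref) - 1, "+" + alt[len(ref):]
    if len(ref) > len(alt) and ref.startswith(alt):
        return pos0 + len(alt), f"-{len(ref) - len(alt)}"
    return None  # complex allele: not representable, skipped


def load_allele_map(path) -> dict:
    """Site -> alleles map from a VCF (positions + ALTs) or a tab-separated
    file with columns contig, 1-based position, allele.  Keys are
    ``(contig, 0-based position)``; values are sets of allele strings."""
    path = str(path)
    mapping: dict = {}
    if path.endswith((".vcf", ".vcf.gz")):
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    conv = _alt_to_allele(rec.ref, alt, rec.pos - 1)
                    if conv is not None:
                        pos, allele = conv
                        mapping.setdefault((rec.contig, pos), set()).add(allele)
        return mapping
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected contig, position, allele")
            contig, pos1, allele = parts[0], int(parts[1]), parts[2]
            mapping.setdefault((contig, pos1 - 1), set()).add(allele)
    return mapping


def write_allele_map(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tposition\tallele\n")
        for (contig, pos), alleles in sorted(mapping.items()):
            for allele in sorted(alleles):
                fh.write(f"{contig}\t{pos + 1}\t{allele}\n")


def write_run_metadata(result, path) -> None:
    """JSON sidecar with test counts, null parameters, seed and config."""
    meta = {
        "n_tests": result.n_tests,
        "n_tests_total": int(sum(result.n_tests.values())),
        "n_sites_gated": result.n_sites_gated,
        "null_params": {
            m: {"alpha": p.alpha, "beta": p.beta, "sites_used": p.sites_used}
            for m, p in result.null_params.items()
            if p is not None
        },
        "seed": result.seed,
        "config": result.config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
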