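"""Readers and writers for every external representation the pipeline touches.

Dialect rules are explicit:

* VCF dosages come from the per-sample ``DS`` FORMAT field and the coded
  allele is ALT; TSV dosage tables have a header of variant ids and one row
  per sample, with variant metadata supplied by an optional sidecar table.
* Network edge lists use the STRING dialect: ``node  node  combined_score``
  with integer scores 0–1000; the confidence filter is strict (> threshold).
* Gene annotation is either BED (0-based half-open) or a 1-based inclusive
  TSV; everything is normalised to 1-based inclusive on ingest.
* Summary-statistic TSVs round-trip to 6 significant digits.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    GeneModel,
    GenotypeMatrix,
    ValidationError,
    Variant,
)

# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _check_dosages(dosage: np.ndarray, variants: list[Variant],
                   samples: list[str]) -> None:
    with np.errstate(invalid="ignore"):
        bad = (dosage < 0) | (dosage > 2)
    if np.any(bad):
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"dosage {dosage[i, j]} outside [0, 2] for sample {samples[i]!r}, "
            f"variant {variants[j].id!r}"
        )


def read_genotypes(path, dialect: str = "tsv_dosage",
                   variant_meta: Optional[pd.DataFrame] = None) -> GenotypeMatrix:
    """Read a dosage matrix.

    Parameters
    ----------
    dialect
        ``"vcf_dosage"``: VCF 4.x with a per-sample ``DS`` field; the coded
        allele is ALT. ``"tsv_dosage"``: tab-separated, header of variant
        ids, first column sample id.
    variant_meta
        Optional table with columns ``id, chrom, pos, coded_allele,
        other_allele`` (and optionally ``missense``) supplying metadata for
        the TSV dialect, which carries none itself. Without it, placeholder
        metadata (chrom ``"NA"``, pos 1, alleles A/B) is attached.
    """
    if dialect == "vcf_dosage":
        return _read_vcf_dosage(path)
    if dialect == "tsv_dosage":
        return _read_tsv_dosage(path, variant_meta)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf_dosage(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise FormatError(f"{rec.ID or rec.POS}: record has no DS field")
        col = np.asarray(ds, dtype=float).reshape(-1)
        col = np.where(col < 0, np.nan, col)  # cyvcf2 encodes missing as negative
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        variants.append(
            Variant(
                id=vid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                coded_allele=rec.ALT[0],
                other_allele=rec.REF,
            )
        )
        columns.append(col)
    if not variants:
        raise FormatError(f"{path}: VCF contains no variant records")
    dosage = np.column_stack(columns)
    _check_dosages(dosage, variants, samples)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def _read_tsv_dosage(path, variant_meta: Optional[pd.DataFrame]) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"{path}: cannot parse TSV dosage table: {exc}") from exc
    if df.columns.empty:
        raise FormatError(f"{path}: no variant columns in header")
    meta = {}
    if variant_meta is not None:
        meta = {str(r["id"]): r for _, r in variant_meta.iterrows()}
    variants = []
    for vid in df.columns:
        if vid in meta:
            r = meta[vid]
            variants.append(
                Variant(
                    id=str(vid), chrom=str(r["chrom"]), pos=int(r["pos"]),
                    coded_allele=str(r["coded_allele"]),
                    other_allele=str(r["other_allele"]),
                    missense=bool(r.get("missense", False)),
                )
            )
        else:
            variants.append(Variant(id=str(vid), chrom="NA", pos=1,
                                    coded_allele="A", other_allele="B"))
    dosage = df.to_numpy(dtype=float)
    samples = [str(s) for s in df.index]
    _check_dosages(dosage, variants, samples)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the TSV dosage dialect (header of variant ids, one row/sample)."""
    df = pd.DataFrame(gm.dosage, index=gm.samples,
                      columns=[v.id for v in gm.variants])
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def read_network(path, min_confidence: int = 400) -> nx.Graph:
    """Read a STRING-style edge list, keeping edges with score > min_confidence.

    Duplicate pairs keep the maximum confidence; nodes whose every edge is
    filtered out are retained as isolated nodes. An empty file yields an
    empty graph.
    """
    g = nx.Graph()
    best: dict[frozenset, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 'node node score'")
            a, b, score_s = parts[0], parts[1], parts[2]
            try:
                score = int(score_s)
            except ValueError:
                if lineno == 1:  # tolerate a header line
                    continue
                raise FormatError(
                    f"{path}:{lineno}: non-integer score {score_s!r}"
                ) from None
            if not (0 <= score <= 1000):
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if a == b:
                continue  # self-loops are not representable
            g.add_node(a)
            g.add_node(b)
            key = frozenset((a, b))
            if score > best.get(key, -1):
                best[key] = score
    for key, score in best.items():
        if score > min_confidence:
            a, b = sorted(key)
            g.add_edge(a, b, confidence=score)
    return g


def write_network(g: nx.Graph, path) -> None:
    # isolated nodes are not representable in an edge list and are dropped
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{int(d['confidence'])}\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path, dialect: str = "bed") -> list[GeneModel]:
    """Read gene models; ``dialect`` is ``"bed"`` (0-based half-open) or
    ``"one_based"`` (TSV with header gene_id, symbol, chrom, start, end,
    strand). Coordinates are normalised to 1-based inclusive."""
    genes: list[GeneModel] = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or parts[0].startswith(("#", "track", "browser")):
                    continue
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
                chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
                strand = parts[5] if len(parts) >= 6 else "+"
                try:
                    start_i, end_i = int(start) + 1, int(end)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from None
                genes.append(GeneModel(gene_id=name, symbol=name, chrom=chrom,
                                       start=start_i, end=end_i, strand=strand))
    elif dialect == "one_based":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "symbol", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for _, r in df.iterrows():
            genes.append(
                GeneModel(gene_id=str(r["gene_id"]), symbol=str(r["symbol"]),
                          chrom=str(r["chrom"]), start=int(r["start"]),
                          end=int(r["end"]), strand=str(r["strand"]))
            )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path) -> None:
    """Write the 1-based inclusive TSV dialect."""
    rows = [
        {"gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
         "start": g.start, "end": g.end, "strand": g.strand}
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

SUMSTATS_COLUMNS = ["id", "chrom", "pos", "coded_allele", "other_allele",
                    "trait", "beta", "se", "p", "n"]

#: smallest positive normal double; p-value underflow clamps here
P_FLOOR = float(np.finfo(float).tiny)


def validate_sumstats(df: pd.DataFrame, source: str = "<sumstats>") -> pd.DataFrame:
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "id"].iloc[0]
        raise ValidationError(f"{source}: se <= 0 at variant {bad!r}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "id"].iloc[0]
        raise ValidationError(
            f"{source}: p outside (0, 1] at variant {bad!r} "
            f"(underflow must be stored as the smallest positive float)"
        )
    return df


def read_sumstats(path) -> pd.DataFrame:
    """Read a summary-statistic TSV (id, chrom, pos, alleles, trait, beta,
    se, p, n; extra columns are preserved)."""
    df = pd.read_csv(path, sep="\t")
    return validate_sumstats(df, source=str(path))


def write_sumstats(df: pd.DataFrame, path) -> None:
    validate_sumstats(df)
    out = df.copy()
    for col in ("beta", "se", "p"):
        out[col] = out[col].map(lambda x: f"{x:.6g}")
    out.to_csv(path, sep="\t", index=False)


def zscore_p(beta: float, se: float) -> float:
    """Two-sided normal tail p for beta/se, clamped at the float floor."""
    from scipy.stats import norm

    z = abs(beta / se)
    p = 2.0 * norm.sf(z)
    return max(p, P_FLOOR)


def check_sumstats_consistency(df: pd.DataFrame, rel_tol: float = 0.05) -> pd.Series:
    """Flag rows whose stored p disagrees with 2*Phi(-|beta/se|).

    Rows at the underflow floor are never flagged (the stored p is a clamp,
    not a measurement).
    """
    expected = df.apply(lambda r: zscore_p(r["beta"], r["se"]), axis=1)
    stored = df["p"].astype(float)
    at_floor = stored <= P_FLOOR * 2
    with np.errstate(divide="ignore"):
        rel = np.abs(np.log(stored) - np.log(expected)) / np.abs(np.log(expected))
    return pd.Series(np.where(at_floor, False, rel > rel_tol), index=df.index)
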