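"""Readers, writers and the typed in-memory containers for every external
format the pipeline touches.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere inside the package
  (variant names follow the ``chrom:pos:ref:alt`` style); BED input is
  converted at the boundary.
* Animals are joined across files by identifier, never by row order.
  Animals missing from any required file are dropped with a logged count —
  unbalanced trait records are the norm in the designs this tool targets.
* Missing phenotype cells use the token ``"NA"`` by default.
* Dosage-TSV dialect: first column is the animal id, one column per variant,
  header cells ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cmgwas")

MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A record does not parse under the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Animals × variants allele-dosage matrix with variant metadata.

    ``dosages`` holds counts of the alternative allele in [0, 2]; ``nan``
    marks a missing genotype. ``variant_meta`` is a DataFrame with columns
    ``chrom, pos, ref, alt, id`` (pos 1-based), sorted by position within
    each chromosome.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    animal_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.animal_ids):
            raise ValidationError(
                f"{n} dosage rows but {len(self.animal_ids)} animal ids")
        if len(self.animal_ids) != len(set(self.animal_ids)):
            raise ValidationError("duplicate animal ids")
        if m != len(self.variant_meta):
            raise ValidationError(
                f"{m} dosage columns but {len(self.variant_meta)} variant rows")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValidationError("dosages outside [0, 2]")
        keys = self.variant_keys()
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chrom, pos, alt) variant keys")
        for chrom, sub in self.variant_meta.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on {chrom}")

    # -- convenience -------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_keys(self) -> list[str]:
        vm = self.variant_meta
        return [variant_key(c, p, r, a) for c, p, r, a in
                zip(vm["chrom"], vm["pos"], vm["ref"], vm["alt"])]

    def key_index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.variant_keys())}

    def chrom_of(self) -> np.ndarray:
        return self.variant_meta["chrom"].to_numpy()

    def positions(self) -> np.ndarray:
        return self.variant_meta["pos"].to_numpy()

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx],
                              self.variant_meta.iloc[idx].reset_index(drop=True),
                              list(self.animal_ids))

    def subset_animals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        order = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [order[a] for a in ids]
        return GenotypeMatrix(self.dosages[rows], self.variant_meta.copy(),
                              list(ids))


@dataclass
class PhenotypeTable:
    """Animals × traits matrix of pre-adjusted phenotypes; nan = missing."""

    values: np.ndarray
    trait_names: list[str]
    animal_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trait_names = [str(t) for t in self.trait_names]
        self.animal_ids = [str(a) for a in self.animal_ids]
        if len(self.trait_names) != len(set(self.trait_names)):
            raise ValidationError("duplicate trait names")
        if self.values.shape != (len(self.animal_ids), len(self.trait_names)):
            raise ValidationError("phenotype matrix shape mismatch")
        if np.any(np.isinf(self.values)):
            raise ValidationError("non-finite phenotype value")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def records_per_trait(self) -> dict[str, int]:
        counts = np.sum(~np.isnan(self.values), axis=0)
        return dict(zip(self.trait_names, (int(c) for c in counts)))

    def subset_animals(self, ids: Sequence[str]) -> "PhenotypeTable":
        order = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [order[a] for a in ids]
        return PhenotypeTable(self.values[rows], list(self.trait_names),
                              list(ids))


@dataclass
class StrainMatrix:
    """Animals × strains proportion matrix (the Q matrix of the model).

    Row sums may be below 1 when pedigree knowledge is partial.
    """

    proportions: np.ndarray
    strain_names: list[str]
    animal_ids: list[str]

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.min() < -1e-12 or self.proportions.max() > 1 + 1e-12:
            raise ValidationError("strain proportion outside [0, 1]")
        if np.any(self.proportions.sum(axis=1) > 1 + 1e-9):
            raise ValidationError("strain proportions sum above 1")
        if self.proportions.shape != (len(self.animal_ids), len(self.strain_names)):
            raise ValidationError("strain matrix shape mismatch")

    def subset_animals(self, ids: Sequence[str]) -> "StrainMatrix":
        order = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [order[a] for a in ids]
        return StrainMatrix(self.proportions[rows], list(self.strain_names),
                            list(ids))


@dataclass
class GeneSet:
    """Gene intervals, 1-based inclusive coordinates."""

    table: pd.DataFrame  # columns: chrom, start, end, name, strand

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end", "name"):
            if col not in t.columns:
                raise ValidationError(f"gene table missing column {col!r}")
        if "strand" not in t.columns:
            t = t.assign(strand=".")
        if len(t) and np.any(t["start"].to_numpy() > t["end"].to_numpy()):
            raise ValidationError("gene with start > end")
        if len(t) and (t["name"].astype(str).str.len() == 0).any():
            raise ValidationError("gene with empty name")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | os.PathLike, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT and/or DS) or the dosage-TSV dialect.

    VCF genotypes are converted to 0/1/2 counts of the alternative allele;
    a DS (dosage) FORMAT field takes precedence over GT when present.
    Multiallelic records are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    animal_ids = list(vcf.samples)
    cols, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or drop it upstream")
        try:
            ds = rec.format("DS")
        except KeyError:   # DS absent from the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = rec.gt_types
            col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        cols.append(col)
        meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                     rec.ID or variant_key(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])))
    if not cols:
        raise FormatError(f"no records in {path}")
    vm = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt", "id"])
    return GenotypeMatrix(np.column_stack(cols), vm, animal_ids)


def _parse_dosage_header(cell: str, colno: int) -> tuple[str, int, str, str]:
    parts = cell.split(":")
    if len(parts) != 4:
        raise FormatError(
            f"dosage-TSV header column {colno} is not chrom:pos:ref:alt: {cell!r}")
    chrom, pos, ref, alt = parts
    try:
        return chrom, int(pos), ref, alt
    except ValueError as exc:
        raise FormatError(f"bad position in header column {colno}: {cell!r}") from exc


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[MISSING_TOKEN])
    if df.shape[1] < 2:
        raise FormatError(f"{path}: dosage TSV needs an id column and ≥1 variant")
    animal_ids = df.iloc[:, 0].tolist()
    meta = [_parse_dosage_header(c, i + 2) for i, c in enumerate(df.columns[1:])]
    vm = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    vm["id"] = [variant_key(*m) for m in meta]
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(dos, vm, animal_ids)


def write_genotypes(gm: GenotypeMatrix, path: str | os.PathLike,
                    format: str = "vcf") -> None:
    path = os.fspath(path)
    if format == "dosage-tsv":
        df = pd.DataFrame(gm.dosages, columns=gm.variant_keys())
        df.insert(0, "animal_id", gm.animal_ids)
        df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
                  float_format="%.6g")
        return
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")
    vm = gm.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(vm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternative allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.animal_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(gm.n_variants):
            row = vm.iloc[j]
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT:DS"]
            for d in gm.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    gt = gt_map.get(int(round(d))) if abs(d - round(d)) < 1e-9 else "./."
                    fields.append(f"{gt or './.'}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes / strains
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | os.PathLike,
                    missing_token: str = MISSING_TOKEN) -> PhenotypeTable:
    """Read a pre-adjusted phenotype TSV (id column + one column per trait)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str}, keep_default_na=False,
                     na_values=[missing_token])
    animal_ids = df.iloc[:, 0].tolist()
    traits = list(df.columns[1:])
    try:
        vals = df.iloc[:, 1:].apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(
            f"{path}: non-numeric phenotype cell (missing token is "
            f"{missing_token!r}): {exc}") from exc
    tab = PhenotypeTable(vals, traits, animal_ids)
    logger.info("read %d animals × %d traits; records per trait: %s",
                len(animal_ids), len(traits), tab.records_per_trait())
    return tab


def write_phenotypes(tab: PhenotypeTable, path: str | os.PathLike,
                     missing_token: str = MISSING_TOKEN) -> None:
    df = pd.DataFrame(tab.values, columns=tab.trait_names)
    df.insert(0, "animal_id", tab.animal_ids)
    df.to_csv(os.fspath(path), sep="\t", index=False, na_rep=missing_token,
              float_format="%.10g")


def read_strains(path: str | os.PathLike) -> StrainMatrix:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    props = df.iloc[:, 1:].to_numpy(dtype=float)
    return StrainMatrix(props, list(df.columns[1:]), df.iloc[:, 0].tolist())


def write_strains(sm: StrainMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(sm.proportions, columns=sm.strain_names)
    df.insert(0, "animal_id", sm.animal_ids)
    df.to_csv(os.fspath(path), sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def read_genes(path: str | os.PathLike, format: str = "bed") -> GeneSet:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    BED coordinates are shifted to the package's 1-based inclusive convention.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format == "bed":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if df.shape[1] < 4:
            raise FormatError(f"{path}: BED needs ≥4 columns (chrom start end name)")
        out = pd.DataFrame({
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,   # 0-based half-open → 1-based incl.
            "end": df[2].astype(int),
            "name": df[3].astype(str),
            "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
        })
        return GeneSet(out)
    if format == "gff3":
        import gffutils

        db = gffutils.create_db(path, ":memory:", force=True,
                                merge_strategy="create_unique")
        rows = []
        for feat in db.features_of_type("gene"):
            name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
            rows.append((feat.seqid, feat.start, feat.end, name, feat.strand or "."))
        return GeneSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                   "name", "strand"]))
    raise ValueError(f"unknown gene format {format!r}")


def write_genes(genes: GeneSet, path: str | os.PathLike) -> None:
    """Write genes as BED (converting back to 0-based half-open)."""
    t = genes.table
    out = pd.DataFrame({
        "chrom": t["chrom"], "start": t["start"] - 1, "end": t["end"],
        "name": t["name"], "score": 0, "strand": t["strand"],
    })
    out.to_csv(os.fspath(path), sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_assoc(assoc, path: str | os.PathLike) -> None:
    """Write an association table as TSV: one row per variant, per-trait
    effect/SE/t/P column blocks in stable order."""
    cols = {"variant": assoc.variant_keys,
            "chrom": assoc.chrom, "pos": assoc.pos}
    for k, trait in enumerate(assoc.trait_names):
        cols[f"{trait}.effect"] = assoc.effects[:, k]
        cols[f"{trait}.se"] = assoc.se[:, k]
        cols[f"{trait}.t"] = assoc.t[:, k]
        cols[f"{trait}.p"] = assoc.p[:, k]
    pd.DataFrame(cols).to_csv(os.fspath(path), sep="\t", index=False,
                              na_rep=MISSING_TOKEN, float_format="%.8g")


def read_assoc(path: str | os.PathLike):
    """Read an association table written by :func:`write_assoc`."""
    from .mlm_engine import AssocTable

    df = pd.read_csv(os.fspath(path), sep="\t", keep_default_na=False,
                     na_values=[MISSING_TOKEN])
    traits = [c[:-7] for c in df.columns if c.endswith(".effect")]
    eff = np.column_stack([df[f"{t}.effect"].to_numpy(float) for t in traits])
    se = np.column_stack([df[f"{t}.se"].to_numpy(float) for t in traits])
    tv = np.column_stack([df[f"{t}.t"].to_numpy(float) for t in traits])
    pv = np.column_stack([df[f"{t}.p"].to_numpy(float) for t in traits])
    return AssocTable(variant_keys=df["variant"].tolist(),
                      chrom=df["chrom"].to_numpy(),
                      pos=df["pos"].to_numpy(int),
                      trait_names=traits, effects=eff, se=se, t=tv, p=pv)


QTL_COLUMNS = ["variant", "chrom", "pos", "cycle", "multi_trait_p",
               "multi_trait_chisq", "n_significant_traits", "ld_n_members",
               "ld_region_span_bp", "nearest_genes"]


def format_gene_label(name: str, distance_bp: int) -> str:
    """``RALY^16`` style label: gene name with its distance in kb."""
    kb = distance_bp / 1000.0
    txt = f"{kb:g}"
    return f"{name}^{txt}"


def write_qtl(records, path: str | os.PathLike,
              trait_names: Sequence[str] | None = None) -> None:
    """Write selected putative causal variants: one row per variant with its
    selection cycle, multi-trait P, masked per-trait signed t profile,
    LD-region span and nearest genes (distance in bp alongside the kb label).
    """
    trait_names = list(trait_names) if trait_names is not None else (
        list(records[0].trait_names) if records else [])
    rows = []
    for r in records:
        genes = ";".join(f"{g.gene}:{g.distance}" for g in r.genes)
        labels = " ".join(format_gene_label(g.gene, g.distance) for g in r.genes)
        row = {"variant": r.key, "chrom": r.chrom, "pos": r.pos,
               "cycle": r.cycle, "multi_trait_p": r.meta_p,
               "multi_trait_chisq": r.chisq,
               "n_significant_traits": r.profile.n_significant,
               "ld_n_members": len(r.ld_members),
               "ld_region_span_bp": r.ld_span,
               "nearest_genes": genes, "gene_labels": labels}
        masked = r.profile.masked()
        for trait, val in zip(trait_names, masked):
            row[f"t.{trait}"] = "" if val is None else f"{val:.4g}"
        rows.append(row)
    cols = QTL_COLUMNS + ["gene_labels"] + [f"t.{t}" for t in trait_names]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(os.fspath(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_animals(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                  strains: StrainMatrix
                  ) -> tuple[GenotypeMatrix, PhenotypeTable, StrainMatrix]:
    """Intersect the three inputs on animal id, preserving genotype order.

    Animals absent from any input are dropped (count logged).
    """
    common = [a for a in genotypes.animal_ids
              if a in set(phenotypes.animal_ids) and a in set(strains.animal_ids)]
    dropped = (len(set(genotypes.animal_ids) | set(phenotypes.animal_ids)
                   | set(strains.animal_ids)) - len(common))
    if dropped:
        logger.info("align_animals: dropped %d animals absent from ≥1 input",
                    dropped)
    if not common:
        raise ValidationError("no animals shared across genotype/phenotype/strain inputs")
    return (genotypes.subset_animals(common),
            phenotypes.subset_animals(common),
            strains.subset_animals(common))
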