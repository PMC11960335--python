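"""Readers and writers for the pipeline's file formats.

Formats touched: a minimal VCF v4.2 subset (CHROM, POS, REF, ALT and the GT
FORMAT field only; multi-allelic sites must be pre-split), 6-column
pre-MAKEPED PED pedigrees, and TSV tables for annotations, population
frequencies and expression series.  Reading a VCF goes through :mod:`pysam`;
writing emits plain text.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .models import (
    INSILICO_TOOLS,
    POPULATIONS,
    AnnotationRecord,
    GenotypeCall,
    PopulationFrequency,
    Trio,
    Variant,
    VariantKey,
)

logger = logging.getLogger(__name__)

# Integer genotype codes used in the cohort matrix.
HOM_REF, HET, HOM_ALT, HEMI, MISSING = 0, 1, 2, 3, -1

_CODE_TO_ZYGOSITY = {
    HOM_REF: "hom_ref",
    HET: "het",
    HOM_ALT: "hom_alt",
    HEMI: "hemi",
    MISSING: "missing",
}
_ZYGOSITY_TO_CODE = {v: k for k, v in _CODE_TO_ZYGOSITY.items()}

#: Chromosome labels treated as sex chromosomes for hemizygosity.
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})

#: Default allele numbers used when a frequency cell is missing, of the order
#: of a large exome-aggregate reference and its subsets.
DEFAULT_ALLELE_NUMBER = {
    "all": 250000,
    "control": 109000,
    "eas_all": 19000,
    "eas_control": 9000,
}


@dataclass
class Cohort:
    """Trios plus a dense genotype matrix (samples x variants).

    ``genotypes[i, j]`` is the integer code of sample ``samples[i]`` at
    ``variants[j]``; ``mendelian_inconsistent[t, j]`` flags trio ``t`` at
    variant ``j`` as unreachable by Mendelian transmission (missing calls are
    never flagged).
    """

    trios: list[Trio]
    samples: list[str]
    variants: list[Variant]
    genotypes: np.ndarray
    sample_sex: dict[str, str] = field(default_factory=dict)
    mendelian_inconsistent: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n_s, n_v = self.genotypes.shape
        if n_s != len(self.samples) or n_v != len(self.variants):
            raise ValueError("genotype matrix shape does not match samples/variants")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {v.key: j for j, v in enumerate(self.variants)}
        if len(self._variant_index) != len(self.variants):
            raise ValueError("duplicate variant key in cohort")

    def genotype_code(self, sample_id: str, key: VariantKey) -> int:
        return int(self.genotypes[self._sample_index[sample_id], self._variant_index[key]])

    def call(self, sample_id: str, key: VariantKey) -> GenotypeCall:
        code = self.genotype_code(sample_id, key)
        return GenotypeCall(sample_id, key, _CODE_TO_ZYGOSITY[code])

    def calls(self) -> Iterable[GenotypeCall]:
        for i, s in enumerate(self.samples):
            for j, v in enumerate(self.variants):
                yield GenotypeCall(s, v.key, _CODE_TO_ZYGOSITY[int(self.genotypes[i, j])])

    def trio_codes(self, trio: Trio, key: VariantKey) -> tuple[int, int, int]:
        """(proband, father, mother) genotype codes at *key*."""
        j = self._variant_index[key]
        return (
            int(self.genotypes[self._sample_index[trio.proband_id], j]),
            int(self.genotypes[self._sample_index[trio.father_id], j]),
            int(self.genotypes[self._sample_index[trio.mother_id], j]),
        )


def transmissible_alleles(code: int) -> set[int]:
    """Alleles a diploid parent with genotype *code* can transmit."""
    return {HOM_REF: {0}, HET: {0, 1}, HOM_ALT: {1}}[code]


def mendelian_consistent(child: int, father: int, mother: int) -> bool:
    """True iff the diploid child genotype is reachable by transmission.

    Any missing or hemizygous call makes the configuration unassessable and
    therefore not flagged; a de novo het (both parents hom_ref) is *not*
    transmission-consistent and is flagged here — interpretation as a de novo
    event is the classifier's job, not the reader's.
    """
    diploid = (HOM_REF, HET, HOM_ALT)
    if child not in diploid or father not in diploid or mother not in diploid:
        return True
    return any(
        f + m == child
        for f in transmissible_alleles(father)
        for m in transmissible_alleles(mother)
    )


def _flag_mendelian(cohort: Cohort) -> np.ndarray:
    flags = np.zeros((len(cohort.trios), len(cohort.variants)), dtype=bool)
    for t, trio in enumerate(cohort.trios):
        for j, v in enumerate(cohort.variants):
            c, f, m = cohort.trio_codes(trio, v.key)
            if not mendelian_consistent(c, f, m):
                flags[t, j] = True
    return flags


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(ped_path: str | Path) -> tuple[list[Trio], list[str], dict[str, str]]:
    """Parse a 6-column PED file into trios, sample order and sample sexes."""
    rows = pd.read_csv(
        ped_path,
        sep=r"\s+",
        header=None,
        names=["family", "sample", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    samples = list(rows["sample"])
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id in PED")
    sexes = {
        r["sample"]: {"1": "male", "2": "female"}.get(str(r["sex"]), "unknown")
        for _, r in rows.iterrows()
    }
    trios = []
    known = set(samples)
    for _, r in rows.iterrows():
        if r["father"] not in ("0", "", None) and r["mother"] not in ("0", "", None):
            for parent in (r["father"], r["mother"]):
                if parent not in known:
                    raise ValueError(f"PED parent {parent!r} has no sample row")
            trios.append(
                Trio(
                    proband_id=r["sample"],
                    father_id=r["father"],
                    mother_id=r["mother"],
                    proband_sex=sexes[r["sample"]] if sexes[r["sample"]] != "unknown" else "male",
                    affected=str(r["phenotype"]) == "2",
                )
            )
    return trios, samples, sexes


def write_ped(cohort: Cohort, ped_path: str | Path) -> None:
    child_of = {t.proband_id: t for t in cohort.trios}
    sex_code = {"male": "1", "female": "2"}
    with open(ped_path, "w") as fh:
        for s in cohort.samples:
            t = child_of.get(s)
            father = t.father_id if t else "0"
            mother = t.mother_id if t else "0"
            fam = t.proband_id if t else next(
                (u.proband_id for u in cohort.trios if s in (u.father_id, u.mother_id)), s
            )
            pheno = "2" if (t and t.affected) else "1"
            fh.write(
                "\t".join(
                    [fam, s, father, mother, sex_code.get(cohort.sample_sex.get(s, "male"), "1"), pheno]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _code_from_gt(gt: tuple, sample_sex: str, chrom: str) -> int:
    alleles = tuple(a for a in gt)
    if any(a is None for a in alleles) or len(alleles) == 0:
        return MISSING
    if len(alleles) == 1:
        if chrom in SEX_CHROMOSOMES and sample_sex == "male":
            return HEMI if alleles[0] == 1 else HOM_REF
        logger.warning("haploid GT on autosome treated as missing")
        return MISSING
    if any(a not in (0, 1) for a in alleles):
        logger.warning("unparseable GT %s treated as missing", alleles)
        return MISSING
    return int(sum(alleles))


def read_trio_genotypes(vcf_path: str | Path, ped_path: str | Path) -> Cohort:
    """Read a cohort from a minimal VCF plus its PED pedigree.

    Every sample named in the PED must be present in the VCF (hard error
    otherwise); un-parseable GT values become ``missing`` with a warning;
    multi-allelic sites are rejected.  Mendelian inconsistencies are flagged
    on the returned cohort, not dropped.
    """
    trios, samples, sexes = read_ped(ped_path)
    vcf = pysam.VariantFile(str(vcf_path))
    vcf_samples = set(vcf.header.samples)
    for s in samples:
        if s not in vcf_samples:
            raise ValueError(f"sample {s!r} named in PED is absent from VCF")

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"multi-allelic or ALT-less site at {rec.chrom}:{rec.pos}; pre-split required"
            )
        v = Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0], gene="")
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            col[i] = _code_from_gt(rec.samples[s]["GT"], sexes.get(s, "male"), rec.chrom)
        variants.append(v)
        columns.append(col)
    vcf.close()

    genotypes = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    cohort = Cohort(
        trios=trios, samples=samples, variants=variants, genotypes=genotypes, sample_sex=sexes
    )
    cohort.mendelian_inconsistent = _flag_mendelian(cohort)
    return cohort


_GT_FROM_CODE = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", HEMI: "1", MISSING: "./."}


def write_vcf(cohort: Cohort, vcf_path: str | Path) -> None:
    """Write the cohort's genotypes as a minimal VCF v4.2 text file."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for v in cohort.variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        order = sorted(range(len(cohort.variants)), key=lambda j: (chroms.index(cohort.variants[j].chrom), cohort.variants[j].pos))
        for j in order:
            v = cohort.variants[j]
            gts = "\t".join(_GT_FROM_CODE[int(g)] for g in cohort.genotypes[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "hgvs_p",
    "protein_pos", "ref_aa", "alt_aa", "consequence",
    "splice_residue", "splice_length_effect", "ddg", "hbond_changes",
]


def annotation_columns() -> list[str]:
    cols = list(_BASE_COLUMNS)
    cols += [f"verdict_{t}" for t in INSILICO_TOOLS]
    for pop in POPULATIONS:
        cols += [f"ac_{pop}", f"an_{pop}", f"hom_{pop}"]
    return cols


def _is_blank(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() in ("", "-", ".")


def _parse_int(x, column: str) -> int:
    try:
        val = int(float(x))
    except (TypeError, ValueError):
        raise ValueError(f"malformed numeric cell {x!r} in column {column}")
    return val


def read_annotation_table(
    tsv_path: str | Path,
    default_allele_number: Optional[dict[str, int]] = None,
) -> dict[VariantKey, AnnotationRecord]:
    """Read a per-variant annotation TSV into AnnotationRecords.

    Missing frequency cells (blank or ``-``) become ``allele_count = 0``
    against the population's default allele number; malformed numbers,
    negative counts and duplicate variant keys are errors.
    """
    defaults = dict(DEFAULT_ALLELE_NUMBER)
    if default_allele_number:
        defaults.update(default_allele_number)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    records: dict[VariantKey, AnnotationRecord] = {}
    for _, row in df.iterrows():
        protein_pos = None if _is_blank(row.get("protein_pos")) else _parse_int(row["protein_pos"], "protein_pos")
        variant = Variant(
            chrom=str(row["chrom"]),
            pos=_parse_int(row["pos"], "pos"),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            gene=str(row["gene"]),
            transcript=str(row.get("transcript", "")),
            hgvs_c=str(row.get("hgvs_c", "")),
            hgvs_p="" if _is_blank(row.get("hgvs_p")) else str(row["hgvs_p"]),
            protein_pos=protein_pos,
            ref_aa=None if _is_blank(row.get("ref_aa")) else str(row["ref_aa"]),
            alt_aa=None if _is_blank(row.get("alt_aa")) else str(row["alt_aa"]),
            consequence=str(row.get("consequence", "other")),
        )
        if variant.key in records:
            raise ValueError(f"duplicate variant key {variant.key} in annotation table")
        frequencies = {}
        for pop in POPULATIONS:
            ac_cell, an_cell = row.get(f"ac_{pop}"), row.get(f"an_{pop}")
            hom_cell = row.get(f"hom_{pop}")
            if _is_blank(ac_cell):
                ac, an = 0, defaults[pop]
            else:
                ac = _parse_int(ac_cell, f"ac_{pop}")
                an = defaults[pop] if _is_blank(an_cell) else _parse_int(an_cell, f"an_{pop}")
            hom = 0 if _is_blank(hom_cell) else _parse_int(hom_cell, f"hom_{pop}")
            frequencies[pop] = PopulationFrequency(variant.key, pop, ac, an, hom)
        verdicts = {}
        for tool in INSILICO_TOOLS:
            cell = row.get(f"verdict_{tool}")
            if not _is_blank(cell):
                verdicts[tool] = str(cell)
        records[variant.key] = AnnotationRecord(
            variant=variant,
            insilico_verdicts=verdicts,
            ddg=None if _is_blank(row.get("ddg")) else float(row["ddg"]),
            hbond_changes=None if _is_blank(row.get("hbond_changes")) else _parse_int(row["hbond_changes"], "hbond_changes"),
            frequencies=frequencies,
            splice_residue=None if _is_blank(row.get("splice_residue")) else _parse_int(row["splice_residue"], "splice_residue"),
            splice_length_effect=str(row.get("splice_length_effect", "")).strip().lower() in ("1", "true", "yes"),
        )
    return records


def write_annotation_table(
    records: dict[VariantKey, AnnotationRecord] | Sequence[AnnotationRecord],
    tsv_path: str | Path,
) -> None:
    if isinstance(records, dict):
        records = list(records.values())
    rows = []
    for rec in records:
        v = rec.variant
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "transcript": v.transcript, "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p or "",
            "protein_pos": "" if v.protein_pos is None else v.protein_pos,
            "ref_aa": v.ref_aa or "", "alt_aa": v.alt_aa or "",
            "consequence": v.consequence,
            "splice_residue": "" if rec.splice_residue is None else rec.splice_residue,
            "splice_length_effect": "true" if rec.splice_length_effect else "",
            "ddg": "" if rec.ddg is None else rec.ddg,
            "hbond_changes": "" if rec.hbond_changes is None else rec.hbond_changes,
        }
        for tool in INSILICO_TOOLS:
            row[f"verdict_{tool}"] = rec.insilico_verdicts.get(tool, "")
        for pop in POPULATIONS:
            f = rec.frequencies.get(pop)
            row[f"ac_{pop}"] = "" if f is None else f.allele_count
            row[f"an_{pop}"] = "" if f is None else f.allele_number
            row[f"hom_{pop}"] = "" if f is None else f.hom_count
        rows.append(row)
    rows.sort(key=lambda r: (r["gene"], r["chrom"], r["pos"], r["ref"], r["alt"]))
    pd.DataFrame(rows, columns=annotation_columns()).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression series
# ---------------------------------------------------------------------------

def read_expression_table(tsv_path: str | Path) -> pd.DataFrame:
    """Read an age-indexed expression TSV with columns region, age, rpkm."""
    df = pd.read_csv(tsv_path, sep="\t")
    missing = {"region", "age", "rpkm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    if (df["rpkm"] < 0).any():
        raise ValueError("negative rpkm value")
    return df


def write_expression_table(df: pd.DataFrame, tsv_path: str | Path) -> None:
    df = df.sort_values(["region", "age"], kind="mergesort")
    df.to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stage outputs + manifest
# ---------------------------------------------------------------------------

def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Write stage-output tables as TSVs plus a run manifest.

    Rows are sorted deterministically (by gene then variant key when those
    columns exist, else by all columns) so identical inputs give
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        df = df.copy()
        sort_cols = [c for c in ("gene", "chrom", "pos", "ref", "alt") if c in df.columns]
        if not sort_cols:
            sort_cols = list(df.columns)
        if len(df) and sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort")
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    manifest = {
        "seed": seed,
        "config": config or {},
        "tables": sorted(tables),
        "versions": {
            "comphet": _package_version(),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return written


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("comphet")
    except Exception:  # pragma: no cover - not installed
        return "unknown"
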