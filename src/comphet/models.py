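"""Core domain types shared across the pipeline.

A *variant* is identified by its ``(chrom, pos, ref, alt)`` key; all tables
(genotypes, annotations, population frequencies) are joined on that key.
Coordinates are 1-based (VCF convention); protein positions are 1-based
residue indices on the annotated transcript's protein product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Consequence classes retained by the consequence filter.  ``other`` covers
#: synonymous, deep-intronic, UTR and any class the analysis discards.
CONSEQUENCES = (
    "canonical_splice",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "missense",
    "initiation_codon",
    "other",
)

#: Consequence classes that carry a protein position.
PROTEIN_POSITIONAL = {"missense", "inframe_indel"}

#: Reference populations, mirroring a gnomAD-style resource: the full cohort,
#: its control-only subset, and the East-Asian slices of both.
POPULATIONS = ("all", "control", "eas_all", "eas_control")

ZYGOSITIES = ("hom_ref", "het", "hom_alt", "hemi", "missing")

#: The nine in-silico damaging-effect predictors whose verdicts are consumed
#: as annotation columns (their internals are upstream of this package).
INSILICO_TOOLS = (
    "MutationTaster",
    "CADD",
    "fitCons",
    "ReVe",
    "GERP++",
    "phyloP",
    "PhastCons",
    "Fathmm-MKL",
    "SiPhy",
)

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Variant:
    """A biallelic sequence variant with its transcript-level annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    protein_pos: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    consequence: str = "other"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.consequence in PROTEIN_POSITIONAL and self.protein_pos is None:
            raise ValueError(
                f"{self.consequence} variant {self.key} requires protein_pos"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        """Human-readable name, preferring HGVS over the genomic key."""
        if self.hgvs_c:
            return f"{self.gene}:{self.hgvs_c}" + (
                f"/{self.hgvs_p}" if self.hgvs_p else ""
            )
        return f"{self.gene}:{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    variant: VariantKey
    zygosity: str

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class Trio:
    proband_id: str
    father_id: str
    mother_id: str
    proband_sex: str = "male"  # {male, female}
    affected: bool = True

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(f"trio ids must be distinct: {ids}")
        if self.proband_sex not in ("male", "female"):
            raise ValueError(f"proband_sex must be male/female, got {self.proband_sex!r}")


@dataclass(frozen=True)
class PopulationFrequency:
    """Allele count / number / homozygote count in one reference population.

    An absent variant is represented with ``allele_count == 0`` against the
    population's default allele number.
    """

    variant: VariantKey
    population: str
    allele_count: int
    allele_number: int
    hom_count: int = 0

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.allele_count < 0 or self.hom_count < 0:
            raise ValueError("negative count")
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if self.allele_count > self.allele_number:
            raise ValueError(
                f"allele_count {self.allele_count} > allele_number {self.allele_number}"
            )
        if self.hom_count > self.allele_count // 2:
            raise ValueError("hom_count exceeds allele_count / 2")

    @property
    def frequency(self) -> float:
        return self.allele_count / self.allele_number


@dataclass
class AnnotationRecord:
    """Per-variant annotation row: consequence-level fields live on the
    Variant; this carries predictor verdicts, biophysical annotations and the
    per-population frequencies."""

    variant: Variant
    insilico_verdicts: dict[str, str] = field(default_factory=dict)
    ddg: Optional[float] = None
    hbond_changes: Optional[int] = None
    frequencies: dict[str, PopulationFrequency] = field(default_factory=dict)
    #: residue used to localize a splice variant on the protein (input column)
    splice_residue: Optional[int] = None
    #: whether a splice variant may alter protein length (input column)
    splice_length_effect: bool = False

    def __post_init__(self) -> None:
        if self.ddg is not None and self.variant.consequence != "missense":
            raise ValueError("ddg only applies to missense variants")
        if self.hbond_changes is not None and self.hbond_changes < 0:
            raise ValueError("hbond_changes must be >= 0")
        for tool, verdict in self.insilico_verdicts.items():
            if verdict not in ("damaging", "benign", "missing"):
                raise ValueError(f"bad verdict {verdict!r} for {tool}")

    def frequency(self, population: str) -> float:
        """Allele frequency in *population*; absent => 0.0 by convention."""
        rec = self.frequencies.get(population)
        return 0.0 if rec is None else rec.frequency

    def allele_count(self, population: str) -> int:
        rec = self.frequencies.get(population)
        return 0 if rec is None else rec.allele_count

    @property
    def damaging_tool_count(self) -> int:
        return sum(1 for v in self.insilico_verdicts.values() if v == "damaging")
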