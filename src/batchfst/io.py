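"""Readers and writers for the cohort's file formats.

VCF 4.2 (GT genotypes; INFO keys AC and AA), a sample-metadata TSV mirroring
the 1000 Genomes sample spreadsheet (sample, pop, super_pop, center), a
functional-annotation TSV with raw predictor categories for SIFT, PolyPhen-2
and MutationAssessor, and Sprime-style introgressed-allele tables
(CHROM, POS, ALLELE, POP).

Variant selection on read follows the cohort-analysis convention: only
biallelic SNVs that are polymorphic across the whole dataset are retained,
and the ALT-copy count AC is recomputed from the genotypes so the AC
invariant (AC equals the sum of dosage codes over non-missing samples)
holds exactly after any read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1
BASES = ("A", "C", "G", "T")
AA_DEGENERATE = (".", "-", "N")

#: Default mapping from raw dbNSFP-style predictor categories to the
#: two-way deleterious/benign classification.  SIFT "D" (deleterious),
#: PolyPhen-2 HDIV "D" (probably damaging) and MutationAssessor "H" (high)
#: count as deleterious; every other category is benign.  The cut is a
#: declared convention, configurable via the pipeline YAML.
DEFAULT_PREDICTOR_MAPPING = {
    "sift": ("D",),
    "polyphen2": ("D",),
    "mutation_assessor": ("H",),
}

DELETERIOUS = "deleterious"
BENIGN = "benign"
ABSENT = "absent"

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ac", "aa", "p1", "p2", "p3", "coding"]


@dataclass
class GenotypeMatrix:
    """Biallelic-SNV genotypes plus per-variant metadata.

    ``genotypes`` has shape (n_variants, n_samples) with ALT-dosage codes
    {0, 1, 2} and -1 for missing.  ``variants`` carries chrom, pos (1-based),
    ref, alt, ac, aa, predictor labels p1/p2/p3 in
    {deleterious, benign, absent} and a boolean coding flag.
    """

    samples: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                "genotypes shape "
                f"{self.genotypes.shape} does not match "
                f"({len(self.variants)} variants, {len(self.samples)} samples)"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def recompute_ac(self) -> np.ndarray:
        """ALT allele copies per variant, missing genotypes contributing 0."""
        g = self.genotypes
        return np.where(g == MISSING, 0, g).sum(axis=1)

    def validate(self) -> None:
        ac = self.recompute_ac()
        if not np.array_equal(ac, self.variants["ac"].to_numpy()):
            raise ValueError("AC flag inconsistent with genotype dosages")
        called = (self.genotypes != MISSING).sum(axis=1)
        mono = (ac == 0) | (ac == 2 * called)
        if mono.any():
            raise ValueError(f"{int(mono.sum())} monomorphic variants present")

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
        )

    def sample_indexer(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[s] for s in sample_ids], dtype=np.intp)


def _is_snv(ref: str, alts: list[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in BASES
        and alts[0].upper() in BASES
    )


def read_vcf(path: str) -> GenotypeMatrix:
    """Load a VCF, keeping only biallelic polymorphic SNVs.

    Multi-allelic records, non-SNVs and records monomorphic over the whole
    dataset are dropped (counts in ``filter_log``).  AC is recomputed from
    the genotypes; a malformed or missing AA flag is replaced by the
    absent-code '.'.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF carries no samples / GT field")
    rows, genos = [], []
    dropped = {"multiallelic": 0, "non_snv": 0, "monomorphic": 0}
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1:
            dropped["multiallelic"] += 1
            continue
        if not _is_snv(var.REF, alts):
            dropped["non_snv"] += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        called = int((g != MISSING).sum())
        ac = int(np.where(g == MISSING, 0, g).sum())
        if ac == 0 or ac == 2 * called:
            dropped["monomorphic"] += 1
            continue
        aa = var.INFO.get("AA")
        if not isinstance(aa, str) or aa == "":
            aa = "."
        rows.append((var.CHROM, var.POS, var.REF, alts[0], ac, aa))
        genos.append(g)
    vcf.close()
    if dropped and any(dropped.values()):
        logger.info("read_vcf(%s): dropped %s", path, dropped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "aa"])
    variants["p1"] = ABSENT
    variants["p2"] = ABSENT
    variants["p3"] = ABSENT
    variants["coding"] = False
    gm = GenotypeMatrix(
        samples=samples,
        variants=variants,
        genotypes=np.asarray(genos, dtype=np.int8).reshape(len(rows), len(samples)),
        filter_log={"dropped": dropped, "kept": len(rows)},
    )
    return gm


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (INFO AC and AA, FORMAT GT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AC,Number=A,Type=Integer,'
            'Description="Alternate allele count across genotypes">\n'
        )
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        v = gm.variants
        for i in range(gm.n_variants):
            row = v.iloc[i]
            gts = "\t".join(_GT_STRING[int(g)] for g in gm.genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"AC={row.ac};AA={row.aa}\tGT\t{gts}\n"
            )


def read_metadata(path: str) -> pd.DataFrame:
    """Sample metadata TSV (sample, pop, super_pop, center), indexed by sample.

    Samples with a missing sequencing center are excluded and reported in
    ``attrs['excluded_samples']`` (the cohort convention: every analysed
    sample has exactly one center).  Duplicate sample IDs are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "pop", "super_pop", "center"}
    if df.empty:
        raise ValueError(f"{path}: empty metadata table")
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dups = df["sample"][df["sample"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups}")
    missing_center = df["center"].isna() | (df["center"].str.strip() == "")
    excluded = df.loc[missing_center, "sample"].tolist()
    if excluded:
        logger.info("read_metadata(%s): excluding %d samples without a center: %s",
                    path, len(excluded), excluded)
    out = df.loc[~missing_center].set_index("sample")[["pop", "super_pop", "center"]]
    out.attrs["excluded_samples"] = excluded
    return out


def write_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False
    )


def check_consistency(gm: GenotypeMatrix, metadata: pd.DataFrame) -> list[str]:
    """Samples genotyped in the VCF but absent from the metadata table."""
    missing = [s for s in gm.samples if s not in metadata.index]
    if missing:
        logger.warning("%d genotyped samples missing from metadata: %s",
                       len(missing), missing)
    return missing


def read_annotations(
    path: str,
    gm: GenotypeMatrix,
    mapping: dict | None = None,
) -> GenotypeMatrix:
    """Merge a predictor-annotation TSV into the variant table (in place).

    The TSV carries raw categories (columns chrom, pos, sift, polyphen2,
    mutation_assessor); ``mapping`` lists, per predictor, the categories
    that count as deleterious (default :data:`DEFAULT_PREDICTOR_MAPPING`).
    Variants without an annotation row keep absent labels and are treated
    as non-coding.
    """
    mapping = mapping or DEFAULT_PREDICTOR_MAPPING
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})
    ann = ann.set_index(["chrom", "pos"])
    key = pd.MultiIndex.from_frame(gm.variants[["chrom", "pos"]].astype({"chrom": str}))
    for col, pred in zip(("p1", "p2", "p3"), ("sift", "polyphen2", "mutation_assessor")):
        raw = ann[pred].reindex(key)
        labels = np.where(
            raw.isna(), ABSENT,
            np.where(raw.isin(mapping[pred]), DELETERIOUS, BENIGN),
        )
        gm.variants[col] = labels
    gm.variants["coding"] = key.isin(ann.index)
    return gm


def write_annotations(gm: GenotypeMatrix, path: str,
                      mapping: dict | None = None) -> None:
    """Write raw predictor categories for the coding variants.

    Inverse of :func:`read_annotations` under the default mapping:
    deleterious labels become the first deleterious category of each
    predictor, benign labels a representative tolerated category.
    """
    mapping = mapping or DEFAULT_PREDICTOR_MAPPING
    benign_code = {"sift": "T", "polyphen2": "B", "mutation_assessor": "L"}
    v = gm.variants
    coding = v[v["coding"]]
    out = pd.DataFrame({
        "chrom": coding["chrom"],
        "pos": coding["pos"],
        "sift": np.where(coding["p1"] == DELETERIOUS, mapping["sift"][0],
                         benign_code["sift"]),
        "polyphen2": np.where(coding["p2"] == DELETERIOUS, mapping["polyphen2"][0],
                              benign_code["polyphen2"]),
        "mutation_assessor": np.where(coding["p3"] == DELETERIOUS,
                                      mapping["mutation_assessor"][0],
                                      benign_code["mutation_assessor"]),
    })
    out.to_csv(path, sep="\t", index=False)


def read_sprime_table(
    path: str,
    gm: GenotypeMatrix | None = None,
    case_sensitive_alleles: bool = False,
) -> dict[tuple[str, int, str], str]:
    """Sprime-style TSV (CHROM, POS, ALLELE, POP) as a lookup map.

    One entry per (variant, population); duplicates are rejected.  When a
    genotype matrix is supplied, rows whose position is absent from it or
    whose allele matches neither REF nor ALT are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "POS": int,
                                            "ALLELE": str, "POP": str})
    required = {"CHROM", "POS", "ALLELE", "POP"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: Sprime table needs columns {sorted(required)}")
    keys = list(zip(df["CHROM"], df["POS"], df["POP"]))
    if len(keys) != len(set(keys)):
        raise ValueError(f"{path}: duplicate (CHROM, POS, POP) entries")
    lookup = None
    if gm is not None:
        v = gm.variants
        lookup = {
            (str(c), int(p)): (r, a)
            for c, p, r, a in zip(v["chrom"].astype(str), v["pos"], v["ref"], v["alt"])
        }
    table: dict[tuple[str, int, str], str] = {}
    skipped = {"unmatched_position": 0, "allele_mismatch": 0}
    for (chrom, pos, pop), allele in zip(keys, df["ALLELE"]):
        if lookup is not None:
            hit = lookup.get((str(chrom), int(pos)))
            if hit is None:
                skipped["unmatched_position"] += 1
                continue
            ref, alt = hit
            ok = (allele in (ref, alt)) if case_sensitive_alleles else (
                allele.upper() in (ref.upper(), alt.upper()))
            if not ok:
                skipped["allele_mismatch"] += 1
                logger.warning("Sprime row %s:%s %s (%s) matches neither REF nor ALT",
                               chrom, pos, allele, pop)
                continue
        table[(str(chrom), int(pos), str(pop))] = str(allele)
    if any(skipped.values()):
        logger.info("read_sprime_table(%s): skipped %s", path, skipped)
    return table


def write_sprime_table(table: pd.DataFrame | dict, path: str) -> None:
    if isinstance(table, dict):
        table = pd.DataFrame(
            [(c, p, a, pop) for (c, p, pop), a in sorted(table.items())],
            columns=["CHROM", "POS", "ALLELE", "POP"],
        )
    table.to_csv(path, sep="\t", index=False)
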