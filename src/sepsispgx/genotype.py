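"""Composite biomarker classification, ancestry PCA and plate layout.

Each improved-response polymorphism (IRP) is a composite of two SNPs:
IRP A pairs rs684923 (RYR2, chr 1) with rs3751501 (ACIN1, chr 14);
IRP B pairs rs3179969 (SPATA7, chr 14) with rs640098 (FLI1, chr 11).
A patient is biomarker positive when at least one component SNP carries
its responsive genotype.  The responsive genotype sets are
configuration: only rs3751501's (AA|AG) is publicly documented, so
synthetic runs declare all four explicitly.

A 93-SNP ancestry-informative-marker (AIM) panel is reduced to
principal components that enter the primary model as covariates against
population stratification.  Genotyping plate layouts are randomized but
keep every matched set on a single plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DataError

IRP_STATUS_POSITIVE = "positive"
IRP_STATUS_NEGATIVE = "negative"
IRP_STATUS_INDETERMINATE = "indeterminate"


def normalize_genotype(genotype: str) -> str:
    """Canonical unordered representation: alleles sorted, e.g. GA -> AG."""
    if len(genotype) != 2:
        raise DataError(f"genotype must be two alleles, got {genotype!r}")
    return "".join(sorted(genotype))


@dataclass(frozen=True)
class SNPDefinition:
    snp_id: str
    alleles: tuple[str, str]
    responsive_genotypes: frozenset[str]

    def __post_init__(self):
        norm = frozenset(normalize_genotype(g) for g in self.responsive_genotypes)
        object.__setattr__(self, "responsive_genotypes", norm)
        valid = self.possible_genotypes()
        if not norm or not norm <= valid:
            raise ValueError(
                f"{self.snp_id}: responsive genotypes {sorted(norm)} must be a "
                f"nonempty subset of {sorted(valid)}"
            )

    def possible_genotypes(self) -> frozenset[str]:
        a, b = self.alleles
        return frozenset({normalize_genotype(a + a), normalize_genotype(a + b),
                          normalize_genotype(b + b)})


@dataclass(frozen=True)
class IRPDefinition:
    irp_id: str
    snps: tuple[SNPDefinition, SNPDefinition]

    def __post_init__(self):
        if len(self.snps) != 2:
            raise ValueError("an IRP is a composite of exactly 2 SNPs")


def default_irp_definitions() -> dict[str, IRPDefinition]:
    """Synthetic-study defaults.  rs3751501's responsive set (AA|AG) is
    the documented one; the other three are declared for simulation
    (responsive = minor-allele carrier)."""
    return {
        "A": IRPDefinition(
            "A",
            (
                SNPDefinition("rs684923", ("C", "T"), frozenset({"TT", "CT"})),
                SNPDefinition("rs3751501", ("A", "G"), frozenset({"AA", "AG"})),
            ),
        ),
        "B": IRPDefinition(
            "B",
            (
                SNPDefinition("rs3179969", ("A", "G"), frozenset({"AA", "AG"})),
                SNPDefinition("rs640098", ("C", "T"), frozenset({"TT", "CT"})),
            ),
        ),
    }


@dataclass
class IRPStatus:
    patient_id: str
    irp_id: str
    status: str


def classify_irp(
    calls: Mapping[str, Optional[str]],
    definition: IRPDefinition,
    patient_id: str = "",
) -> IRPStatus:
    """Composite OR rule over the two component SNPs.

    positive: at least one present call is responsive.
    negative: both calls present and neither responsive.
    indeterminate: any missing call without a responsive present call.
    """
    statuses = []
    for snp in definition.snps:
        g = calls.get(snp.snp_id)
        if g is None or g == "":
            statuses.append(None)
            continue
        g = normalize_genotype(g)
        if g not in snp.possible_genotypes():
            raise DataError(
                f"{snp.snp_id}: genotype {g!r} uses an undeclared allele "
                f"(alleles {snp.alleles})"
            )
        statuses.append(g in snp.responsive_genotypes)
    if any(s is True for s in statuses):
        status = IRP_STATUS_POSITIVE
    elif all(s is False for s in statuses):
        status = IRP_STATUS_NEGATIVE
    else:
        status = IRP_STATUS_INDETERMINATE
    return IRPStatus(patient_id=patient_id, irp_id=definition.irp_id, status=status)


def classify_all(
    genotypes: Mapping[str, Mapping[str, Optional[str]]],
    definitions: Mapping[str, IRPDefinition] | None = None,
) -> pd.DataFrame:
    """IRP status table (patient_id, irp_id, status) for every patient."""
    defs = definitions or default_irp_definitions()
    rows = []
    for pid in sorted(genotypes):
        for irp_id in sorted(defs):
            st = classify_irp(genotypes[pid], defs[irp_id], pid)
            rows.append({"patient_id": pid, "irp_id": irp_id, "status": st.status})
    return pd.DataFrame(rows, columns=["patient_id", "irp_id", "status"])


# ---------------------------------------------------------------------------
# genotype file IO

def write_genotype_tsv(
    genotypes: Mapping[str, Mapping[str, Optional[str]]],
    path: str | Path,
) -> None:
    """Three-column TSV: patient_id, snp_id, genotype (empty = missing)."""
    rows = []
    for pid in sorted(genotypes):
        for snp in sorted(genotypes[pid]):
            g = genotypes[pid][snp]
            rows.append((pid, snp, "" if g is None else g))
    pd.DataFrame(rows, columns=["patient_id", "snp_id", "genotype"]).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_tsv(path: str | Path) -> dict[str, dict[str, Optional[str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("patient_id", "snp_id", "genotype"):
        if col not in df.columns:
            raise DataError(f"genotype TSV missing column {col!r}")
    out: dict[str, dict[str, Optional[str]]] = {}
    for pid, snp, g in df.itertuples(index=False):
        out.setdefault(pid, {})[snp] = g if g else None
    return out


def write_vcf(
    genotypes: Mapping[str, Mapping[str, Optional[str]]],
    snp_alleles: Mapping[str, tuple[str, str]],
    path: str | Path,
) -> None:
    """Minimal VCFv4.2 writer: one record per SNP, diploid unphased GT."""
    patients = sorted(genotypes)
    snps = sorted(snp_alleles)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(patients) + "\n")
        for i, snp in enumerate(snps, start=1):
            ref, alt = snp_alleles[snp]
            fields = ["1", str(i * 1000), snp, ref, alt, ".", "PASS", ".", "GT"]
            for pid in patients:
                g = genotypes[pid].get(snp)
                if g is None:
                    fields.append("./.")
                else:
                    g = normalize_genotype(g)
                    idx = sorted("01"[a == alt] for a in g)
                    fields.append("/".join(idx))
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> dict[str, dict[str, Optional[str]]]:
    """Read diploid GT calls from a VCFv4.2 file into allele-pair strings.

    Phased separators are accepted and the resulting pair is unordered.
    Uses cyvcf2 when available, otherwise a plain-text fallback.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is normally present
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: dict[str, dict[str, Optional[str]]] = {p: {} for p in samples}
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(samples, variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                out[sample][variant.ID] = None
            else:
                out[sample][variant.ID] = normalize_genotype(alleles[a] + alleles[b])
    return out


def _read_vcf_text(path: str | Path) -> dict[str, dict[str, Optional[str]]]:
    out: dict[str, dict[str, Optional[str]]] = {}
    samples: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                out = {s: {} for s in samples}
                continue
            snp_id, ref, alt = parts[2], parts[3], parts[4]
            alleles = [ref] + alt.split(",")
            for sample, cell in zip(samples, parts[9:]):
                gt = cell.split(":")[0].replace("|", "/")
                ab = gt.split("/")
                if "." in ab or len(ab) != 2:
                    out[sample][snp_id] = None
                else:
                    out[sample][snp_id] = normalize_genotype(
                        alleles[int(ab[0])] + alleles[int(ab[1])]
                    )
    return out


# ---------------------------------------------------------------------------
# AIM panel PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame          # patients x k
    explained_variance: np.ndarray
    dropped_snps: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def aim_pca(dosages: pd.DataFrame, k: int = 3) -> PCAResult:
    """Principal components of the AIM genotype-dosage matrix.

    Columns (SNPs) coded 0/1/2 copies of the alternate allele.  SNPs
    with >= 20% missingness or no variation are dropped with a log
    entry; remaining missing dosages are mean-imputed.  Each column is
    centered and scaled by 1/sqrt(p(1-p)) with p the sample allele
    frequency, then the sample covariance is eigen-decomposed.  Sign
    convention: each component's largest-magnitude loading is positive,
    so scores are reproducible up to patient ordering.
    """
    X = dosages.astype(float)
    dropped, log = [], []
    keep = []
    for col in X.columns:
        v = X[col]
        miss = v.isna().mean()
        if miss >= 0.20:
            dropped.append(col)
            log.append(f"SNP {col} dropped: missingness {miss:.0%}")
            continue
        if v.dropna().nunique() <= 1:
            dropped.append(col)
            log.append(f"SNP {col} dropped: monomorphic")
            continue
        keep.append(col)
    X = X[keep]
    M = X.to_numpy(dtype=float)
    col_means = np.nanmean(M, axis=0)
    inds = np.where(np.isnan(M))
    M[inds] = np.take(col_means, inds[1])
    p_hat = np.clip(col_means / 2.0, 1e-6, 1 - 1e-6)
    Z = (M - col_means) / np.sqrt(p_hat * (1 - p_hat))

    n = Z.shape[0]
    C = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > 1e-10))
    if k > rank:
        raise ValueError(f"requested {k} components but rank is {rank}")
    evecs = evecs[:, :k]
    # deterministic sign: largest-|loading| entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Z @ evecs
    shares = evals[:k] / evals.sum()
    return PCAResult(
        scores=pd.DataFrame(scores, index=dosages.index,
                            columns=[f"PC{j + 1}" for j in range(k)]),
        explained_variance=shares,
        dropped_snps=dropped,
        log=log,
    )


def dosage_matrix(
    genotypes: Mapping[str, Mapping[str, Optional[str]]],
    snp_alleles: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Patients x SNPs alternate-allele dosage (0/1/2, NaN when missing)."""
    patients = sorted(genotypes)
    snps = sorted(snp_alleles)
    M = np.full((len(patients), len(snps)), np.nan)
    for i, pid in enumerate(patients):
        calls = genotypes[pid]
        for j, snp in enumerate(snps):
            g = calls.get(snp)
            if g:
                alt = snp_alleles[snp][1]
                M[i, j] = sum(a == alt for a in g)
    return pd.DataFrame(M, index=patients, columns=snps)


# ---------------------------------------------------------------------------
# plate layout

@dataclass
class PlateLayout:
    assignments: pd.DataFrame  # patient_id, set_id, plate, well
    n_plates: int


def _well_labels(capacity: int) -> list[str]:
    n_rows = math.ceil(capacity / 12)
    labels = []
    for r in range(n_rows):
        for c in range(1, 13):
            labels.append(f"{chr(ord('A') + r)}{c}")
    return labels[:capacity]


def assign_plates(matches: Iterable, plate_capacity: int = 96,
                  seed: int = 0) -> PlateLayout:
    """Randomized plate layout that never splits a matched set.

    Sets are shuffled (seeded) and placed whole by first-fit onto
    plates; wells within a plate are then shuffled.  Identical seed
    gives an identical layout.
    """
    matches = list(matches)
    rng = np.random.default_rng(seed)
    sizes = {m.set_id: m.size for m in matches}
    too_big = [s for s, n in sizes.items() if n > plate_capacity]
    if too_big:
        raise ValueError(f"matched sets larger than plate capacity: {too_big}")

    order = sorted(matches, key=lambda m: m.set_id)
    rng.shuffle(order)
    plates: list[list] = []
    space: list[int] = []
    for m in order:
        placed = False
        for i in range(len(plates)):
            if space[i] >= m.size:
                plates[i].append(m)
                space[i] -= m.size
                placed = True
                break
        if not placed:
            plates.append([m])
            space.append(plate_capacity - m.size)

    rows = []
    for p_idx, plate_sets in enumerate(plates, start=1):
        members = []
        for m in plate_sets:
            members.append((m.set_id, m.treated_id))
            members.extend((m.set_id, c) for c in m.control_ids)
        wells = _well_labels(plate_capacity)
        idx = rng.permutation(len(wells))[: len(members)]
        idx.sort()
        well_order = rng.permutation(len(members))
        for (set_id, pid), w in zip(
            [members[i] for i in well_order], [wells[i] for i in idx]
        ):
            rows.append({"patient_id": pid, "set_id": set_id,
                         "plate": p_idx, "well": w})
    return PlateLayout(
        assignments=pd.DataFrame(rows, columns=["patient_id", "set_id",
                                                "plate", "well"]),
        n_plates=len(plates),
    )


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg exact test (diagnostic only), via chi-square with
    continuity on small counts replaced by scipy's exact binom when tiny."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return float("nan")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    mask = exp > 0
    chi2 = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    from scipy import stats as _st
    return float(_st.chi2.sf(chi2, df=1))
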