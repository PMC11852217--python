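"""SNP quality control and imputation-concordance assessment.

QC stages follow chip-data practice: drop loci without map positions or on
sex chromosomes, then filter on per-SNP call rate, minor allele frequency
and a Hardy-Weinberg chi-square test, keeping an ordered ledger of how many
loci each stage removed.  Concordance between an imputed panel and a
sequenced truth set is scored per locus as the fraction of individuals
whose dosage matches exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import MISSING, GenotypeMatrix

SEX_CHROMS = {"X", "Y", "x", "y", "23", "24"}


@dataclass
class QCThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1); got {v}")


@dataclass
class QCLedger:
    initial_snps: int
    removed_by_stage: dict[str, int] = field(default_factory=dict)

    @property
    def final_snps(self) -> int:
        return self.initial_snps - sum(self.removed_by_stage.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.removed_by_stage.values()):
            raise ValueError("stage removal counts must be non-negative")
        if self.final_snps < 0:
            raise ValueError("ledger arithmetic is inconsistent")

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {
                "initial_snps": self.initial_snps,
                "removed_by_stage": self.removed_by_stage,
                "final_snps": self.final_snps,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class ConcordanceReport:
    per_snp_accuracy: np.ndarray
    binned_ranges: dict[float, tuple[float, float]]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_snp_accuracy))

    def perfect_snps(self) -> np.ndarray:
        """Indices of loci with accuracy exactly 1, flaggable for retention."""
        return np.flatnonzero(self.per_snp_accuracy == 1.0)


def snp_stats(geno: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Per-SNP call rate, MAF, and Hardy-Weinberg chi-square p-value.

    MAF uses the allele frequency among non-missing calls; HWE is the 1-df
    chi-square of observed vs expected genotype counts.  All-missing (or
    monomorphic, for HWE) SNPs get NaN and are flagged in ``undefined``.
    """
    if geno.n_individuals < 2:
        raise ValueError("need at least two individuals for SNP statistics")
    d = geno.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0).astype(np.float64)
    call_rate = n_obs / geno.n_individuals

    n0 = ((d == 0) & observed).sum(axis=0).astype(np.float64)
    n1 = (d == 1).sum(axis=0).astype(np.float64)
    n2 = (d == 2).sum(axis=0).astype(np.float64)

    with np.errstate(invalid="ignore", divide="ignore"):
        f = (2 * n2 + n1) / (2 * n_obs)  # frequency of allele a1
        maf = np.minimum(f, 1.0 - f)

        exp0 = n_obs * (1 - f) ** 2
        exp1 = n_obs * 2 * f * (1 - f)
        exp2 = n_obs * f**2
        chi2 = np.zeros(geno.n_snps)
        for obs, exp in ((n0, exp0), (n1, exp1), (n2, exp2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 = chi2 + term
    hwe_p = stats.chi2.sf(chi2, df=1)

    undefined = n_obs == 0
    monomorphic = (maf == 0) | undefined
    maf = np.where(undefined, np.nan, maf)
    hwe_p = np.where(monomorphic, np.nan, hwe_p)
    # exact-HWE loci: chi2 == 0 -> p exactly 1
    return {
        "call_rate": call_rate,
        "maf": maf,
        "hwe_p": hwe_p,
        "undefined": undefined,
    }


def apply_qc(
    geno: GenotypeMatrix,
    thr: QCThresholds | None = None,
    drop_sex_chroms: bool = True,
) -> tuple[GenotypeMatrix, QCLedger]:
    """Staged SNP filter: position/sex-chromosome, call rate, MAF, HWE.

    Stages run in order on the survivors of the previous stage, so MAF and
    HWE are computed on call-rate-passing loci (PLINK-like staging).
    """
    thr = thr or QCThresholds()
    thr.validate()
    ledger = QCLedger(initial_snps=geno.n_snps)

    meta = geno.snp_meta
    bad_pos = meta["pos"].isna() | (meta["pos"] <= 0)
    if drop_sex_chroms:
        bad_pos |= meta["chrom"].astype(str).isin(SEX_CHROMS)
    keep = np.flatnonzero(~bad_pos.to_numpy())
    ledger.removed_by_stage["position_or_sex_chrom"] = geno.n_snps - keep.size
    cur = geno.subset_snps(keep)

    st = snp_stats(cur)
    ok = st["call_rate"] >= thr.min_call_rate
    ledger.removed_by_stage["call_rate"] = int((~ok).sum())
    cur = cur.subset_snps(np.flatnonzero(ok))

    st = snp_stats(cur)
    ok = np.nan_to_num(st["maf"], nan=-1.0) >= thr.min_maf
    ledger.removed_by_stage["maf"] = int((~ok).sum())
    cur = cur.subset_snps(np.flatnonzero(ok))

    st = snp_stats(cur)
    ok = np.nan_to_num(st["hwe_p"], nan=1.0) >= thr.hwe_alpha
    ledger.removed_by_stage["hwe"] = int((~ok).sum())
    cur = cur.subset_snps(np.flatnonzero(ok))

    ledger.validate()
    if cur.n_snps == 0:
        raise ValueError("quality control removed every SNP")
    return cur, ledger


def imputation_concordance(
    imputed: GenotypeMatrix,
    truth: GenotypeMatrix,
    sample_subset: list[str] | None = None,
    bin_thresholds: tuple[float, ...] = (0.3, 0.6, 0.9),
) -> ConcordanceReport:
    """Per-locus fraction of individuals whose dosages match the truth.

    ``bin_thresholds`` partitions loci by minimum accuracy; for each
    threshold the (min, max) accuracy among qualifying loci is reported,
    mirroring how imputation quality is summarised after filtering at
    successively stricter cutoffs.
    """
    if list(imputed.snp_meta["snp_id"]) != list(truth.snp_meta["snp_id"]):
        raise ValueError("imputed and truth matrices must share the same SNP set")
    if sample_subset is None:
        sample_subset = [s for s in imputed.sample_ids if s in set(truth.sample_ids)]
    idx_imp = [imputed.sample_ids.index(s) for s in sample_subset]
    idx_tru = [truth.sample_ids.index(s) for s in sample_subset]
    if not idx_imp:
        raise ValueError("empty sample subset")

    a = imputed.dosages[idx_imp, :]
    b = truth.dosages[idx_tru, :]
    acc = (a == b).mean(axis=0).astype(np.float64)

    ranges: dict[float, tuple[float, float]] = {}
    for t in bin_thresholds:
        sel = acc[acc >= t]
        ranges[t] = (float(sel.min()), float(sel.max())) if sel.size else (np.nan, np.nan)
    return ConcordanceReport(per_snp_accuracy=acc, binned_ranges=ranges)
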