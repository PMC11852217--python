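"""File formats: PLINK bed/bim/fam, phenotype CSV, GCTA-style GRM, truth JSON.

The bed codec implements the standard SNP-major 2-bit layout (magic bytes
``0x6c 0x1b 0x01``): per SNP, genotypes are packed four to a byte with
``00`` = two copies of allele 1, ``10`` = heterozygote, ``11`` = zero
copies, ``01`` = missing.  Dosages here count copies of allele 1 (the bim
A1 allele).  GRMs are written in the GCTA binary-compatible layout: a
``.grm.bin`` of float32 lower-triangle values (row-wise, diagonal
included), a ``.grm.N.bin`` of marker counts, and a ``.grm.id`` text file.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GRMatrix
from .simdata import TraitTruth

# 2-bit codes indexed by dosage of allele1 (0,1,2); missing handled apart
_CODE_BY_DOSAGE = {0: 0b11, 1: 0b10, 2: 0b00, -1: 0b01}
_DOSAGE_BY_CODE = np.array([2, -1, 1, 0], dtype=np.int8)


def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write bed/bim/fam files for a genotype matrix."""
    n, m = geno.n_individuals, geno.n_snps
    bim = pd.DataFrame(
        {
            "chrom": geno.snp_meta["chrom"],
            "snp_id": geno.snp_meta["snp_id"],
            "cm": 0,
            "pos": geno.snp_meta["pos"],
            "a1": geno.snp_meta["a1"],
            "a2": geno.snp_meta["a2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "phen": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    lookup = np.array(
        [_CODE_BY_DOSAGE[0], _CODE_BY_DOSAGE[1], _CODE_BY_DOSAGE[2]], dtype=np.uint8
    )
    codes = np.where(
        geno.dosages < 0, np.uint8(_CODE_BY_DOSAGE[-1]), lookup[np.clip(geno.dosages, 0, 2)]
    ).astype(np.uint8)
    n_bytes = (n + 3) // 4
    padded = np.zeros((n_bytes * 4, m), dtype=np.uint8)
    padded[:n] = codes
    packed = (
        padded[0::4]
        | (padded[1::4] << 2)
        | (padded[2::4] << 4)
        | (padded[3::4] << 6)
    )
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.T.tobytes())  # SNP-major


def read_plink(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phen"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != bytes([0x6C, 0x1B, 0x01]):
            raise ValueError("not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    dosages = _DOSAGE_BY_CODE[codes[:, :n]].T
    snp_meta = bim[["chrom", "pos", "snp_id", "a1", "a2"]].copy()
    return GenotypeMatrix(
        dosages=dosages, snp_meta=snp_meta, sample_ids=fam["iid"].tolist()
    )


def write_gcta_grm(G: GRMatrix, prefix: str, n_snps: int = 0) -> None:
    """GCTA binary-compatible triplet: .grm.bin, .grm.N.bin, .grm.id."""
    n = G.n
    tri = np.concatenate([G.values[i, : i + 1] for i in range(n)]).astype("<f4")
    tri.tofile(f"{prefix}.grm.bin")
    np.full(tri.size, n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": G.sample_ids, "iid": G.sample_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_gcta_grm(prefix: str) -> GRMatrix:
    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(np.float64)
    values = np.zeros((n, n))
    k = 0
    for i in range(n):
        values[i, : i + 1] = tri[k : k + i + 1]
        k += i + 1
    values = values + np.tril(values, -1).T
    return GRMatrix(values=values, sample_ids=ids["iid"].tolist())


def write_weights(snp_ids: list[str], weights: np.ndarray, path: str) -> None:
    pd.DataFrame({"snp_id": snp_ids, "weight": weights}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed_intervals(path: str) -> pd.DataFrame:
    """BED-like chrom/start/end interval file (QTLdb-style prior regions)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    return df


def write_truth(truth: TraitTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "qtl_indices": truth.qtl_indices.tolist(),
                "qtl_effects": truth.qtl_effects.tolist(),
                "true_breeding_values": truth.true_breeding_values.tolist(),
                "realized_h2": truth.realized_h2,
            },
            fh,
        )


def read_truth(path: str) -> TraitTruth:
    with open(path) as fh:
        d = json.load(fh)
    return TraitTruth(
        qtl_indices=np.asarray(d["qtl_indices"], dtype=int),
        qtl_effects=np.asarray(d["qtl_effects"], dtype=float),
        true_breeding_values=np.asarray(d["true_breeding_values"], dtype=float),
        realized_h2=float(d["realized_h2"]),
    )
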