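"""Genotype/phenotype containers, file formats, merging, filtering and scoring.

The central container is :class:`GenotypeDataset`: an individuals x SNP matrix
of allele-1 dosages in {0, 1, 2} (NaN for missing) together with a marker map
(chromosome, 1-based bp position, two allele labels) and per-sample metadata
(sex, origin).  Two on-disk formats are supported and round-trip bit-exactly:

* PLINK bed/bim/fam (SNP-major, magic bytes ``6c 1b 01``);
* a plain-text TSV dialect: header row of SNP ids, first column the sample id,
  cells ``0``/``1``/``2``/``NA``.

Phenotypes live in a tidy table holding left/right Norberg angles (degrees),
their ordinal 0-6 scores under the UK scheme, and the left/right mean score
(multiples of 0.5) that serves as the analysis trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "ScoreScale",
    "read_genotypes",
    "write_genotypes",
    "merge_datasets",
    "maf_filter",
    "allele_frequencies",
    "angle_to_score",
    "mean_lr_score",
    "read_phenotypes",
    "write_phenotypes",
]

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]


@dataclass
class GenotypeDataset:
    """Individuals x SNPs allele-dosage matrix with marker map and sample metadata.

    Parameters
    ----------
    sample_ids : array-like of str
        Ordered unique sample identifiers.
    sample_meta : pandas.DataFrame
        Indexed by sample id; columns ``sex`` ('M'/'F') and ``origin`` plus any
        provenance tags.
    marker_map : pandas.DataFrame
        Columns ``snp_id, chrom, pos, allele1, allele2``; positions 1-based,
        strictly increasing within chromosome.
    dosages : ndarray, shape (n_samples, n_snps)
        Counts of allele1 in {0, 1, 2}; NaN marks missing.
    """

    sample_ids: np.ndarray
    sample_meta: pd.DataFrame
    marker_map: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if len(self.marker_map) != m:
            raise ValueError(f"{len(self.marker_map)} map rows for {m} dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.marker_map["snp_id"].duplicated().any():
            dup = self.marker_map["snp_id"][self.marker_map["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage {self.dosages[i, j]!r} at sample {self.sample_ids[i]!r}, "
                f"SNP {self.marker_map['snp_id'].iloc[j]!r} not in {{0,1,2,NA}}"
            )
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        self.marker_map = self.marker_map.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.marker_map["snp_id"].to_numpy()

    def subset_samples(self, ids) -> "GenotypeDataset":
        ids = list(ids)
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        idx = [lookup[s] for s in ids]
        return GenotypeDataset(
            sample_ids=self.sample_ids[idx],
            sample_meta=self.sample_meta.loc[ids].copy(),
            marker_map=self.marker_map.copy(),
            dosages=self.dosages[idx],
        )

    def subset_snps(self, snp_ids) -> "GenotypeDataset":
        snp_ids = set(snp_ids)
        mask = self.marker_map["snp_id"].isin(snp_ids).to_numpy()
        return GenotypeDataset(
            sample_ids=self.sample_ids.copy(),
            sample_meta=self.sample_meta.copy(),
            marker_map=self.marker_map.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )


def allele_frequencies(d: GenotypeDataset) -> np.ndarray:
    """Per-SNP frequency of allele1 over non-missing dosages (NaN if all missing)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(d.dosages, axis=0) / 2.0


# ---------------------------------------------------------------------------
# Norberg-angle scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreScale:
    """UK-scheme conversion of a Norberg angle (degrees) to an ordinal 0-6 score.

    A healthy hip with angle above ``breakpoints[0]`` (105 degrees) scores 0; an
    angle below ``breakpoints[-1]`` (79 degrees) scores 6.  The intermediate
    bands default to six equal-width intervals over (79, 105]; the original
    tabulation is not universally available, so the breakpoints are
    configurable for users who hold it.
    """

    breakpoints: tuple = tuple(np.round(np.linspace(105.0, 79.0, 7), 6))

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if len(bp) != 7:
            raise ValueError("ScoreScale needs 7 descending breakpoints (scores 0..6)")
        if any(bp[i] <= bp[i + 1] for i in range(6)):
            raise ValueError("breakpoints must be strictly decreasing")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def upper_healthy(self) -> float:
        return self.breakpoints[0]

    @property
    def lower_severe(self) -> float:
        return self.breakpoints[-1]


def angle_to_score(angle, scale: ScoreScale | None = None):
    """Convert Norberg angle(s) in degrees to UK-scheme ordinal score(s) 0-6.

    Monotone non-increasing in the angle: score 0 for angles above (or equal
    to) the healthy threshold, 6 below the severe threshold.  An angle exactly
    on a breakpoint takes the lower (healthier) score.
    """
    scale = scale or ScoreScale()
    a = np.asarray(angle, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if not np.isfinite(a).all():
        raise ValueError("angle must be finite")
    bp = np.asarray(scale.breakpoints)
    # score s iff bp[s] >= angle > bp[s+1]; angles on a breakpoint take the
    # healthier score, so count breakpoints strictly greater than the angle
    score = np.sum(bp[None, :] > a[:, None], axis=-1)
    score = np.clip(score - 1, 0, 6)
    score = np.where(a >= bp[0], 0, score)
    score = np.where(a < bp[-1], 6, score)
    return int(score[0]) if scalar else score


def mean_lr_score(left, right):
    """Mean of left/right hip scores; one missing side falls back to the other.

    Returns ``(mean, flag)`` where ``flag`` is True when only one side was
    available.  Output is a multiple of 0.5 when both sides are integers 0-6.
    """
    lmiss = left is None or (isinstance(left, float) and np.isnan(left))
    rmiss = right is None or (isinstance(right, float) and np.isnan(right))
    if lmiss and rmiss:
        raise ValueError("both hip scores missing")
    if lmiss or rmiss:
        return (float(right if lmiss else left), True)
    for s in (left, right):
        if not (0 <= s <= 6):
            raise ValueError(f"score {s} outside 0..6")
    return ((float(left) + float(right)) / 2.0, False)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit codes, SNP-major: 00 hom A1 (dosage 2), 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _write_plink(d: GenotypeDataset, prefix: Path) -> None:
    prefix = Path(prefix)
    n, m = d.dosages.shape
    codes = np.where(np.isnan(d.dosages), 1, 0).astype(np.uint8)
    codes[d.dosages == 2.0] = 0b00
    codes[d.dosages == 1.0] = 0b10
    codes[d.dosages == 0.0] = 0b11
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.astype(np.uint8).tobytes())
    bim = d.marker_map.assign(cm=0)[["chrom", "snp_id", "cm", "pos", "allele1", "allele2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    sexcode = d.sample_meta["sex"].map({"M": 1, "F": 2}).fillna(0).astype(int)
    origin = (d.sample_meta["origin"].to_numpy(object)
              if "origin" in d.sample_meta.columns else np.full(n, "0", object))
    fam = pd.DataFrame(
        {
            "fid": origin,
            "iid": d.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": sexcode.to_numpy(),
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def _read_plink(prefix: Path) -> GenotypeDataset:
    prefix = Path(prefix)
    try:
        bim = pd.read_csv(
            prefix.with_suffix(".bim"),
            sep=r"\s+",
            header=None,
            names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
            dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
        )
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed bim file {prefix.with_suffix('.bim')}: {exc}") from exc
    if bim[["pos"]].isna().any().any():
        bad = int(bim["pos"].isna().idxmax()) + 1
        raise ValueError(f"malformed bim line {bad}: missing position")
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(
                f"{prefix.with_suffix('.bed')}: bad magic {magic.hex()} "
                "(expected 6c1b01, SNP-major)"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    nbytes = (n + 3) // 4
    if raw.size != m * nbytes:
        raise ValueError(f"bed payload {raw.size} bytes, expected {m * nbytes}")
    raw = raw.reshape(m, nbytes)
    codes = np.empty((m, nbytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    meta = pd.DataFrame(
        {"sex": fam["sex"].map({1: "M", 2: "F"}).to_numpy(object),
         "origin": fam["fid"].to_numpy(object)},
        index=pd.Index(fam["iid"].to_numpy(object), name="sample_id"),
    )
    mm = bim[["snp_id", "chrom", "pos", "allele1", "allele2"]].copy()
    return GenotypeDataset(fam["iid"].to_numpy(object), meta, mm, dosages)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _write_tsv(d: GenotypeDataset, prefix: Path) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame(d.dosages, index=d.sample_ids, columns=d.snp_ids)
    with np.errstate(invalid="ignore"):
        df = df.astype("Int64")
    df.index.name = "sample_id"
    df.to_csv(prefix.with_suffix(".geno.tsv"), sep="\t", na_rep="NA")
    d.marker_map.to_csv(prefix.with_suffix(".map.tsv"), sep="\t", index=False)
    meta = d.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t")


def _read_tsv(prefix: Path) -> GenotypeDataset:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".geno.tsv"), sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    vals = df.to_numpy(object)
    dosages = np.empty(vals.shape, dtype=float)
    for (i, j), v in np.ndenumerate(vals):
        if v == "NA" or v is None:
            dosages[i, j] = np.nan
        elif v in ("0", "1", "2"):
            dosages[i, j] = float(v)
        else:
            raise ValueError(
                f"non-integer dosage {v!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
    mm = pd.read_csv(
        prefix.with_suffix(".map.tsv"),
        sep="\t",
        dtype={"snp_id": str, "chrom": str, "allele1": str, "allele2": str},
    )
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index_col=0, dtype=str)
    return GenotypeDataset(df.index.to_numpy(object), meta, mm, dosages)


def write_genotypes(d: GenotypeDataset, prefix, format: str = "plink-bed") -> None:
    """Write a dataset as PLINK bed/bim/fam or the TSV dialect (``format``)."""
    if format == "plink-bed":
        _write_plink(d, Path(prefix))
    elif format == "tsv":
        _write_tsv(d, Path(prefix))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_genotypes(prefix, format: str = "plink-bed") -> GenotypeDataset:
    """Read a dataset written by :func:`write_genotypes`; bit-exact round trip."""
    if format == "plink-bed":
        return _read_plink(Path(prefix))
    if format == "tsv":
        return _read_tsv(Path(prefix))
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Merging & filtering
# ---------------------------------------------------------------------------

def merge_datasets(a: GenotypeDataset, b: GenotypeDataset, logger=None) -> GenotypeDataset:
    """Merge two datasets on shared (chromosome, position) markers.

    Only the intersection of markers is kept.  Allele labels are harmonised:
    where one input's allele1/allele2 are swapped relative to the other, its
    dosages are flipped (2 - d).  Markers whose allele pairs neither match nor
    swap (including strand-ambiguous disagreements) are dropped and counted.
    Sample metadata (origin tags) is preserved; a sample id present in both
    inputs is an error.
    """
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise ValueError(f"duplicate sample ids across inputs: {sorted(dup)[:5]}")
    akey = pd.MultiIndex.from_frame(a.marker_map[["chrom", "pos"]])
    bkey = pd.MultiIndex.from_frame(b.marker_map[["chrom", "pos"]])
    common = akey.intersection(bkey)
    if len(common) == 0:
        raise ValueError("no SNPs in common between the two datasets")
    ai = pd.Series(np.arange(len(akey)), index=akey).loc[common].to_numpy()
    bi = pd.Series(np.arange(len(bkey)), index=bkey).loc[common].to_numpy()
    a1 = a.marker_map[["allele1", "allele2"]].to_numpy(object)[ai]
    b1 = b.marker_map[["allele1", "allele2"]].to_numpy(object)[bi]
    same = (a1[:, 0] == b1[:, 0]) & (a1[:, 1] == b1[:, 1])
    swap = (a1[:, 0] == b1[:, 1]) & (a1[:, 1] == b1[:, 0])
    keep = same | swap
    n_dropped = int((~keep).sum())
    if n_dropped and logger is not None:
        logger.warning("dropped %d SNPs with irreconcilable allele pairs", n_dropped)
    ai, bi, swap = ai[keep], bi[keep], swap[keep]
    bdos = b.dosages[:, bi].copy()
    bdos[:, swap] = 2.0 - bdos[:, swap]
    # keep a's genome order (the intersection index may come back sorted)
    order = np.argsort(ai)
    ai, bdos = ai[order], bdos[:, order]
    mm = a.marker_map.iloc[ai].reset_index(drop=True)
    dosages = np.vstack([a.dosages[:, ai], bdos])
    meta = pd.concat([a.sample_meta, b.sample_meta])
    ids = np.concatenate([a.sample_ids, b.sample_ids])
    out = GenotypeDataset(ids, meta, mm, dosages)
    out.n_dropped_snps = n_dropped
    return out


def maf_filter(d: GenotypeDataset, threshold: float = 0.01) -> GenotypeDataset:
    """Retain SNPs with minor allele frequency strictly above ``threshold``.

    Frequencies are recomputed on the current sample set (they are never
    cached across subsetting).  ``threshold`` must lie in [0, 0.5).
    """
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must be in [0, 0.5)")
    p = allele_frequencies(d)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    keep &= ~np.isnan(maf)
    return d.subset_snps(d.snp_ids[keep])


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

PHENO_COLUMNS = [
    "sample_id", "sex", "origin",
    "angle_left", "angle_right", "score_left", "score_right",
    "score_mean", "true_bv",
]


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    cols = [c for c in PHENO_COLUMNS if c in pheno.columns]
    pheno[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str, "origin": str})
    if "score_mean" in df:
        sm = df["score_mean"].dropna()
        if not np.allclose(sm * 2, np.round(sm * 2)):
            raise ValueError("score_mean must be multiples of 0.5")
    return df
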