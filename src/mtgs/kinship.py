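"""Genomic relationship (kinship) construction from coded SNP markers.

Markers are coded -1 / 0 / +1 for minor-homozygous, heterozygous and
major-homozygous genotypes.  The additive relationship matrix follows the
VanRaden construction: column-centre the code matrix and scale by the sum
of expected per-marker binomial variances, so the diagonal averages near
1 + f for a panel with mean inbreeding f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = (-1.0, 0.0, 1.0)

PSD_TOL = 1e-8


class DegenerateInputError(ValueError):
    """Raised when the marker set carries no usable polymorphism."""


@dataclass
class MarkerMatrix:
    """Lines x markers genotype codes with optional missingness (NaN)."""

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray  # float (n, p); NaN marks a missing call
    fractional: bool = False  # True after mean imputation (dosage-like cells)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        observed = self.codes[~np.isnan(self.codes)]
        if self.fractional:
            if observed.size and (observed.min() < -1 or observed.max() > 1):
                raise ValueError("imputed codes must stay within [-1, +1]")
        elif observed.size and not np.isin(observed, VALID_CODES).all():
            bad = np.unique(observed[~np.isin(observed, VALID_CODES)])
            raise ValueError(f"marker codes outside {{-1,0,+1}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.line_ids, columns=self.marker_ids)

    def to_csv(self, path) -> None:
        # empty cells encode missing calls; observed codes as integers
        df = self.to_frame()
        fmt = "%.6g" if self.fractional else "%.0f"
        df.to_csv(path, float_format=fmt, index_label="line_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(
            line_ids=[str(i) for i in df.index],
            marker_ids=[str(c) for c in df.columns],
            codes=df.to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass
class KinshipMatrix:
    """Symmetric additive relationship matrix among lines."""

    line_ids: list[str]
    values: np.ndarray
    stabilized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, ids) -> "KinshipMatrix":
        idx = [self.line_ids.index(i) for i in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.stabilized)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(
            path, index_label="line_id"
        )

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


def impute_missing(markers: MarkerMatrix, method: str = "mean", k: int = 5) -> MarkerMatrix:
    """Fill missing genotype calls.

    ``mean`` replaces each missing cell with the marker's observed mean
    (fractional values allowed downstream, as in a dosage).  ``knn`` fills
    from the ``k`` nearest lines by mean absolute code distance over shared
    observed markers, rounded back to the nearest valid code.
    Observed cells are never altered.
    """
    codes = markers.codes
    miss = markers.missing_mask
    if not miss.any():
        return markers

    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = [markers.marker_ids[j] for j in np.where(n_obs == 0)[0]]
        raise DegenerateInputError(f"markers with no observed calls: {bad}")

    out = codes.copy()
    col_means = np.nanmean(codes, axis=0)
    fractional = False
    if method == "mean":
        out[miss] = np.broadcast_to(col_means, codes.shape)[miss]
        fractional = True
    elif method == "knn":
        n = markers.n_lines
        # pairwise mean |code difference| over markers observed in both lines
        diffs = np.abs(codes[:, None, :] - codes[None, :, :])  # NaN where either missing
        with np.errstate(invalid="ignore"):
            dist = np.nanmean(diffs, axis=2)
        np.fill_diagonal(dist, np.inf)
        dist[np.isnan(dist)] = np.inf  # no shared markers
        for i in range(n):
            cols = np.where(miss[i])[0]
            if cols.size == 0:
                continue
            order = np.argsort(dist[i])
            for j in cols:
                donors = [l for l in order if np.isfinite(dist[i, l]) and not miss[l, j]]
                if donors:
                    val = float(np.mean(codes[donors[:k], j]))
                else:
                    val = col_means[j]
                out[i, j] = float(np.clip(np.rint(val), -1, 1))
    else:
        raise ValueError(f"unknown imputation method: {method!r}")
    return MarkerMatrix(markers.line_ids, markers.marker_ids, out, fractional)


def additive_relationship(
    markers: MarkerMatrix, min_maf: float = 0.0
) -> KinshipMatrix:
    """VanRaden additive relationship: K = W W' / c.

    W is the column-centred code matrix and c = sum_j 2 f_j (1 - f_j) with
    f_j the (imputed) allele frequency of marker j.  Requires a fully
    imputed matrix.  ``min_maf`` optionally drops near-monomorphic markers
    before centring (off by default).
    """
    if markers.missing_mask.any():
        raise ValueError("markers contain missing cells; run impute_missing first")
    codes = markers.codes
    # frequency of the +1 allele from the {-1,0,1} coding
    freq = (codes.mean(axis=0) + 1.0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    if min_maf > 0:
        keep = maf >= min_maf
        codes, freq, maf = codes[:, keep], freq[keep], maf[keep]
        if codes.shape[1] == 0:
            raise DegenerateInputError("no markers left after MAF filtering")
    c = float(np.sum(2.0 * freq * (1.0 - freq)))
    if c <= 0.0:
        raise DegenerateInputError("all markers monomorphic: scaling constant is zero")
    W = codes - codes.mean(axis=0)
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0
    return stabilize_psd(KinshipMatrix(list(markers.line_ids), K))


def stabilize_psd(kin: KinshipMatrix, tol: float = PSD_TOL) -> KinshipMatrix:
    """Shift the spectrum up if K has eigenvalues below -tol.

    Adds (|lambda_min| + 1e-6) I when triggered, so downstream Kronecker
    samplers always see a PSD matrix; the event is logged.
    """
    lam_min = float(np.linalg.eigvalsh(kin.values)[0])
    if lam_min < -tol:
        eps = abs(lam_min) + 1e-6
        logger.warning("kinship not PSD (min eig %.3g); adding %.3g * I", lam_min, eps)
        return KinshipMatrix(kin.line_ids, kin.values + eps * np.eye(kin.n_lines), True)
    return kin


def read_vcf(path) -> MarkerMatrix:
    """Read diploid GT fields from a VCF into -1/0/+1 minor-allele coding.

    Alt dosage 0/1/2 is re-oriented per site so +1 is the major-allele
    homozygote and -1 the minor, matching the panel coding convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
    vcf.close()
    dosage = np.column_stack(rows) if rows else np.empty((len(line_ids), 0))
    codes = np.full_like(dosage, np.nan)
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        obs = col[~np.isnan(col)]
        alt_freq = obs.mean() / 2.0 if obs.size else 0.0
        # hom of the major allele -> +1, het -> 0, hom minor -> -1
        major_hom = 0.0 if alt_freq <= 0.5 else 2.0
        codes[:, j] = np.where(
            np.isnan(col), np.nan, np.where(col == 1.0, 0.0, np.where(col == major_hom, 1.0, -1.0))
        )
    return MarkerMatrix(line_ids, marker_ids, codes)
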