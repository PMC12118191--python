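"""Dataset quality checks and the kinetic-thermodynamic linearity fit.

``bep_fit`` performs the Bronsted-Evans-Polanyi-style proxy fit
``pkoff = alpha' * pKd + beta'`` by ordinary least squares: a strong linear
relation justifies predicting the kinetic quantity from equilibrium-geometry
descriptors.  ``chemical_space`` projects fingerprint rows onto their first
two principal components to visualize ligand diversity, and
``label_summary`` reports the pkoff distribution (histogram, range,
adjusted Fisher-Pearson skewness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BEPFit",
    "ChemicalSpace",
    "DatasetAnalysisError",
    "bep_fit",
    "chemical_space",
    "ecfp_matrix",
    "label_summary",
]


class DatasetAnalysisError(ValueError):
    pass


@dataclass
class BEPFit:
    """Least-squares line pkoff = alpha_prime * pKd + beta_prime."""

    alpha_prime: float
    beta_prime: float
    r2: float
    n: int


@dataclass
class ChemicalSpace:
    """First two fingerprint principal components per molecule."""

    coords: np.ndarray  # (N, 2)
    explained: np.ndarray  # explained-variance fractions, length 2


def bep_fit(dataset) -> BEPFit:
    """OLS fit of pkoff against pKd; entries without pKd are dropped with a warning."""
    pkoff = np.asarray(dataset.pkoff, dtype=float)
    pkd = np.asarray(dataset.pkd, dtype=float)
    keep = np.isfinite(pkd)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} entr(ies) without pKd from the BEP fit",
            stacklevel=2,
        )
    pkoff, pkd = pkoff[keep], pkd[keep]
    if pkoff.size < 3:
        raise DatasetAnalysisError("need >= 3 entries with both pkoff and pKd")
    if np.ptp(pkd) == 0.0:
        raise DatasetAnalysisError("pKd is constant: slope undefined")
    # closed-form OLS (normal equations for one predictor + intercept)
    x_bar, y_bar = pkd.mean(), pkoff.mean()
    alpha = float(np.sum((pkd - x_bar) * (pkoff - y_bar)) / np.sum((pkd - x_bar) ** 2))
    beta = float(y_bar - alpha * x_bar)
    pred = alpha * pkd + beta
    ss_res = float(np.sum((pkoff - pred) ** 2))
    ss_tot = float(np.sum((pkoff - y_bar) ** 2))
    if ss_tot == 0.0:
        raise DatasetAnalysisError("pkoff is constant: r2 undefined")
    return BEPFit(alpha_prime=alpha, beta_prime=beta, r2=1.0 - ss_res / ss_tot, n=pkoff.size)


def chemical_space(fingerprints) -> ChemicalSpace:
    """Project fingerprint count rows onto their first two principal components.

    Accepts any numeric N x d matrix (d >= 2, N >= 3); typically binary
    extended-connectivity fingerprints.  Component orientation follows the
    pretreatment convention (largest-magnitude loading positive), so the
    embedding is reproducible and invariant to duplicating every row.
    """
    fp = np.asarray(fingerprints, dtype=float)
    if fp.ndim != 2 or fp.shape[1] < 2 or fp.shape[0] < 3:
        raise DatasetAnalysisError("fingerprints must be an N x d matrix, N >= 3, d >= 2")
    centered = fp - fp.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise DatasetAnalysisError("all fingerprints identical: chemical space undefined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[:2].copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    coords = centered @ loadings.T
    total = float(np.sum(s**2))
    explained = (s[:2] ** 2) / total
    if explained.shape[0] < 2:  # rank-1 data still yields a 2-vector
        explained = np.pad(explained, (0, 2 - explained.shape[0]))
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return ChemicalSpace(coords=coords, explained=explained)


def label_summary(dataset, bins: int = 10) -> dict:
    """Histogram + descriptive summary of the pkoff label distribution."""
    y = np.asarray(dataset.pkoff, dtype=float)
    if y.size < 1:
        raise DatasetAnalysisError("empty dataset")
    counts, edges = np.histogram(y, bins=bins)
    return {
        "n": int(y.size),
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "min": float(y.min()),
        "max": float(y.max()),
        "mean": float(y.mean()),
        "skewness": float(stats.skew(y, bias=False)) if y.size >= 3 else float("nan"),
    }


def ecfp_matrix(smiles: list[str], radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Extended-connectivity fingerprints (Morgan, radius 2, 2048 bits) from SMILES.

    Requires RDKit; invalid SMILES are a hard error naming the offender.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise DatasetAnalysisError("RDKit is required for SMILES fingerprints") from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DatasetAnalysisError(f"could not parse SMILES {smi!r}")
        fp = gen.GetFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=float))
    return np.vstack(rows)
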