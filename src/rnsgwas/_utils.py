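"""Small shared helpers: seeding, standardization, errors."""

from __future__ import annotations

import zlib

import numpy as np


class RnsgwasError(Exception):
    """Base class for all package errors."""


class FormatError(RnsgwasError):
    """Unreadable or malformed input file."""


class SchemaError(RnsgwasError):
    """Missing or invalid columns in a tabular input."""


class EmptyPanelError(RnsgwasError):
    """No SNPs survive filtering."""


class DegenerateInputError(RnsgwasError):
    """Input has no usable variation (all-constant, zero variance, ...)."""


class MatchingInfeasibleError(RnsgwasError):
    """A target SNP has no matched candidate under the given tolerances."""


def rng_for(seed: int, *keys: str | int) -> np.random.Generator:
    """Derive an independent generator from a base seed and a stream label.

    Distinct labels give decorrelated streams; the same (seed, keys) pair
    always yields the same stream. Derived entropy stays below 2**31.
    """
    entropy = [int(seed) % (2**31)]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()) % (2**31))
        else:
            entropy.append(int(k) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *keys: str | int) -> int:
    """A plain integer seed (< 2**31) derived like :func:`rng_for`."""
    entropy = [int(seed) % (2**31)]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()) % (2**31))
        else:
            entropy.append(int(k) % (2**31))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def allele_frequency(dosage: np.ndarray, missing: int = -1) -> np.ndarray:
    """Alt-allele frequency per SNP from a samples x SNPs dosage matrix.

    Missing entries (sentinel) are ignored. Columns with no observed
    genotype get frequency nan.
    """
    d = np.asarray(dosage, dtype=float)
    obs = d != missing
    n_obs = obs.sum(axis=0)
    total = np.where(obs, d, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)


def standardize_dosage(dosage: np.ndarray, missing: int = -1):
    """Mean-impute missing genotypes and scale to unit binomial variance.

    Each SNP column is centered by 2*p and divided by sqrt(2*p*(1-p)), where
    p is the observed alt-allele frequency — the usual scaling for PCA on
    genotype data. Monomorphic columns come back as all zeros.

    Returns (Z, p_hat, poly_mask).
    """
    d = np.asarray(dosage, dtype=float)
    p = allele_frequency(d, missing=missing)
    p_safe = np.where(np.isnan(p), 0.0, p)
    d = np.where(d == missing, 2.0 * p_safe[None, :], d)
    denom = np.sqrt(2.0 * p_safe * (1.0 - p_safe))
    poly = denom > 0
    z = np.zeros_like(d)
    z[:, poly] = (d[:, poly] - 2.0 * p_safe[poly]) / denom[poly]
    return z, p_safe, poly


def normalize_columns(mat: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit L2 norm (zero columns stay zero)."""
    x = mat - mat.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(x, axis=0)
    nz = norms > 0
    x[:, nz] /= norms[nz]
    return x
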