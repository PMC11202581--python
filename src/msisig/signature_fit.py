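"""Non-negative signature refitting and spectrum comparison.

Each sample's channel-count vector ``c`` is decomposed against a reference
signature matrix ``S`` (channels x signatures, columns summing to 1) by
solving the non-negative least-squares problem

    min || S e - c ||_2   subject to  e >= 0,

so the exposures ``e`` live on the mutation-count scale.  A single NNLS
backend keeps the ID and SBS refits directly comparable.  Group-level
spectra are normalised per sample first and then reduced channel-wise by
the median before cosine comparison against reference signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .indel_catalog import MutationalCatalog


class AlignmentError(ValueError):
    """Catalog and signature channel label sets do not match."""


@dataclass
class SignatureMatrix:
    """Reference signatures: non-negative channels x signatures matrix."""

    channel_labels: list
    signature_names: list
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.channel_labels), len(self.signature_names)):
            raise ValueError("weights shape does not match axes")
        if (self.weights < 0).any():
            raise ValueError("signature weights must be non-negative")
        sums = self.weights.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = [n for n, s in zip(self.signature_names, sums) if abs(s - 1) > 1e-6]
            raise ValueError(f"signature columns must sum to 1: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=pd.Index(self.channel_labels, name="Type"),
                            columns=self.signature_names)

    def column(self, name: str) -> np.ndarray:
        return self.weights[:, self.signature_names.index(name)]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def reindex_channels(self, channel_labels: Sequence) -> "SignatureMatrix":
        mine, theirs = set(self.channel_labels), set(channel_labels)
        if mine != theirs:
            raise AlignmentError(
                f"channel label mismatch; missing={sorted(theirs - mine)[:5]} "
                f"extra={sorted(mine - theirs)[:5]}")
        order = [self.channel_labels.index(l) for l in channel_labels]
        return SignatureMatrix(list(channel_labels), list(self.signature_names),
                               self.weights[order, :])


def load_reference(kind: str) -> SignatureMatrix:
    """Load a bundled reference signature matrix.

    ``kind`` is ``"ID83"`` (18 indel signatures) or ``"SBS96"``.  The
    bundled matrices are synthetic stand-ins with the field-standard
    structure (see their generation in :mod:`msisig.synthetic_data`); any
    channel-compatible COSMIC-format TSV can be substituted via
    :meth:`SignatureMatrix.from_tsv`.
    """
    names = {"ID83": "id83_signatures_synthetic.tsv",
             "SBS96": "sbs96_signatures_synthetic.tsv"}
    if kind not in names:
        raise ValueError(f"kind must be ID83 or SBS96, got {kind!r}")
    resource = files("msisig.data").joinpath(names[kind])
    with resource.open("r") as handle:
        df = pd.read_csv(handle, sep="\t", index_col=0)
    return SignatureMatrix(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class ExposureTable:
    """Per-sample signature exposures from NNLS refitting."""

    sample_ids: list
    signature_names: list
    raw: np.ndarray          # samples x signatures, count scale
    proportions: np.ndarray  # rows sum to 1 (zero rows stay zero)
    residual: np.ndarray     # per-sample Euclidean reconstruction error
    zero_samples: list       # samples whose catalog row was all zero

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.sample_ids, name="sample_id")
        raw = pd.DataFrame(self.raw, index=idx, columns=self.signature_names)
        prop = pd.DataFrame(self.proportions, index=idx,
                            columns=[f"{n}_prop" for n in self.signature_names])
        out = pd.concat([raw, prop], axis=1)
        out["residual"] = self.residual
        return out

    def raw_series(self, signature: str) -> pd.Series:
        if signature not in self.signature_names:
            raise KeyError(f"signature {signature!r} not in exposure table")
        j = self.signature_names.index(signature)
        return pd.Series(self.raw[:, j], index=self.sample_ids, name=signature)


def refit_exposures(catalog: MutationalCatalog, signatures: SignatureMatrix,
                    min_contribution: float = 0.0) -> ExposureTable:
    """Refit each catalog row against the signatures by NNLS.

    ``min_contribution`` optionally zeroes exposures whose proportion falls
    below the threshold (the deconstructSigs-style floor), renormalising the
    remaining proportions; the default 0 keeps the plain NNLS solution.
    """
    sig = signatures.reindex_channels(catalog.channel_labels)
    S = sig.weights
    n, k = len(catalog.sample_ids), len(sig.signature_names)
    raw = np.zeros((n, k))
    residual = np.zeros(n)
    zero_samples = []
    for i in range(n):
        c = catalog.counts[i].astype(float)
        if c.sum() == 0:
            zero_samples.append(catalog.sample_ids[i])
            continue
        raw[i], residual[i] = nnls(S, c)
    totals = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = np.where(totals > 0, raw / np.where(totals > 0, totals, 1), 0.0)
    if min_contribution > 0:
        raw = np.where(proportions < min_contribution, 0.0, raw)
        totals = raw.sum(axis=1, keepdims=True)
        proportions = np.where(totals > 0, raw / np.where(totals > 0, totals, 1), 0.0)
    return ExposureTable(list(catalog.sample_ids), list(sig.signature_names),
                         raw, proportions, residual, zero_samples)


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two non-negative vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def group_median_spectrum(catalog: MutationalCatalog, sample_subset: Sequence) -> pd.Series:
    """Channel-wise median of the per-sample normalised spectra of a group."""
    subset = list(sample_subset)
    if not subset:
        raise ValueError("sample subset is empty")
    frame = catalog.to_frame().loc[subset]
    totals = frame.sum(axis=1)
    usable = frame.loc[totals > 0]
    if usable.empty:
        raise ValueError("all samples in the subset have zero catalogs")
    norm = usable.div(usable.sum(axis=1), axis=0)
    return norm.median(axis=0)


def similarity_to_references(group_spectrum, signatures: SignatureMatrix) -> pd.Series:
    """Cosine similarity of a group spectrum against every reference column."""
    spectrum = np.asarray(group_spectrum, dtype=float)
    scores = {name: cosine_similarity(spectrum, signatures.weights[:, j])
              for j, name in enumerate(signatures.signature_names)}
    return pd.Series(scores).sort_values(ascending=False)
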