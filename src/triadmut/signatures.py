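"""Cutoff-scanning structural fingerprints, SVD reduction, and the Euclidean
pre-filter that prunes expensive superpositions.

A signature is a cumulative count vector over a fragment's atom graph: atoms
are typed by pharmacophore class (8 classes, multi-class membership allowed,
see :mod:`triadmut.chem`), and for every unordered class pair and every
cumulative distance cutoff ``c`` in ``{d_min+step, ..., d_max}`` the entry
counts atom pairs of those classes at distance <= c.  Defaults scan 0–10 Å in
0.1 Å steps (100 bins x 36 class pairs = 3600 features).  The vector length is
a derived property of the parameters, not a fixed constant.

The signature matrix of a database is factored as ``A = U S V^T``; the
retained dimensionality k is the smallest number of leading singular values
reaching a target fraction (default 70%) of the spectrum sum (optionally of
the squared spectrum).  New vectors are reduced by right-singular projection
``x -> x V_k`` and compared by Euclidean distance.  The filter is a
pre-filter only: it prunes candidates before superposition, never replaces
the RMSD verdict.  Distances are computed on raw counts (no normalisation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .chem import CHEM_TABLE_VERSION, PHARMACOPHORE_CLASSES, pharmacophore_classes
from .errors import ConfigError, DegenerateSpectrumError, DimensionError

#: unordered class pairs, fixed order
CLASS_PAIRS = tuple(combinations_with_replacement(PHARMACOPHORE_CLASSES, 2))
_PAIR_INDEX = {frozenset(p) if len(set(p)) > 1 else frozenset([p[0]]): i
               for i, p in enumerate(CLASS_PAIRS)}


@dataclass(frozen=True)
class SignatureParams:
    d_min: float = 0.0
    d_max: float = 10.0
    step: float = 0.1
    table_version: str = CHEM_TABLE_VERSION

    def __post_init__(self):
        if not (self.d_min < self.d_max) or self.step <= 0:
            raise ConfigError(
                f"invalid signature params: d_min={self.d_min}, d_max={self.d_max}, step={self.step}")

    @property
    def n_bins(self) -> int:
        return int(round((self.d_max - self.d_min) / self.step))

    @property
    def n_features(self) -> int:
        return len(CLASS_PAIRS) * self.n_bins

    def cutoffs(self) -> np.ndarray:
        return self.d_min + self.step * np.arange(1, self.n_bins + 1)

    def as_dict(self) -> dict:
        return asdict(self)


def compute_signature(triad, params: SignatureParams | None = None) -> np.ndarray:
    """Cumulative-count fingerprint of one triad pair (all stored atoms:
    the 24 main-chain atoms plus the side chains of n and n')."""
    params = params or SignatureParams()
    atoms = triad.all_atoms()
    n_bins = params.n_bins
    hist = np.zeros((len(CLASS_PAIRS), n_bins), dtype=np.int64)
    classes = [pharmacophore_classes(rn, an) for rn, an, _ in atoms]
    coords = np.asarray([xyz for _, _, xyz in atoms], dtype=float).reshape(-1, 3)
    cutoffs = params.cutoffs()
    for i in range(len(atoms)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off, dist in enumerate(d):
            if dist > params.d_max or dist < params.d_min:
                continue
            j = i + 1 + off
            b = int(np.searchsorted(cutoffs, dist, side="left"))
            if b >= n_bins:
                continue
            seen = set()
            for p in classes[i]:
                for q in classes[j]:
                    idx = _PAIR_INDEX[frozenset((p, q))]
                    if idx not in seen:
                        seen.add(idx)
                        hist[idx, b] += 1
    return np.cumsum(hist, axis=1).ravel()


def signature_matrix(triads, params: SignatureParams | None = None) -> np.ndarray:
    params = params or SignatureParams()
    if not triads:
        return np.zeros((0, params.n_features), dtype=np.int64)
    return np.vstack([compute_signature(t, params) for t in triads])


# ---------------------------------------------------------------------------
# SVD model
# ---------------------------------------------------------------------------

@dataclass
class SVDModel:
    basis: np.ndarray            # (n_features, k) right-singular vectors
    singular_values: np.ndarray  # full spectrum
    k: int
    energy_fraction: float
    criterion: str = "singular"  # or "variance" (squared singular values)

    @property
    def n_features(self) -> int:
        return self.basis.shape[0]


def fit_svd(matrix: np.ndarray, energy_fraction: float = 0.70,
            criterion: str = "singular") -> SVDModel:
    """Factor a signatures x features matrix and retain the smallest k whose
    leading singular values reach ``energy_fraction`` of the spectrum sum."""
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] < 1:
        raise ConfigError("need a 2-D matrix with at least one row")
    if not 0 < energy_fraction <= 1:
        raise ConfigError(f"energy_fraction must be in (0, 1], got {energy_fraction}")
    if criterion not in ("singular", "variance"):
        raise ConfigError(f"unknown SVD criterion {criterion!r}")
    _, s, vt = np.linalg.svd(a, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise DegenerateSpectrumError("all-zero matrix has a degenerate spectrum")
    weights = s ** 2 if criterion == "variance" else s
    cum = np.cumsum(weights) / weights.sum()
    k = int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)
    k = max(1, min(k, int(np.sum(s > s[0] * 1e-12))))
    return SVDModel(basis=vt[:k].T.copy(), singular_values=s, k=k,
                    energy_fraction=energy_fraction, criterion=criterion)


def reduce_signature(vector: np.ndarray, model: SVDModel) -> np.ndarray:
    """Project a signature onto the k retained right-singular directions."""
    v = np.asarray(vector, dtype=float)
    if v.ndim == 1:
        if v.shape[0] != model.n_features:
            raise DimensionError(
                f"signature length {v.shape[0]} != model feature count {model.n_features}")
    elif v.ndim == 2:
        if v.shape[1] != model.n_features:
            raise DimensionError(
                f"signature length {v.shape[1]} != model feature count {model.n_features}")
    else:
        raise DimensionError("expected a vector or a matrix of signatures")
    return v @ model.basis


def fit_database_signatures(db, params: SignatureParams | None = None,
                            energy_fraction: float = 0.70,
                            criterion: str = "singular") -> None:
    """Compute, factor and attach signature artifacts to a TriadDatabase."""
    params = params or SignatureParams()
    db.signature_params = params
    db.signature_matrix = signature_matrix(db.representatives, params)
    if len(db.representatives) == 0 or not np.any(db.signature_matrix):
        db.svd_model = None
        db.reduced_matrix = None
        return
    db.svd_model = fit_svd(db.signature_matrix, energy_fraction, criterion)
    db.reduced_matrix = reduce_signature(db.signature_matrix, db.svd_model)


def filter_candidates(target_reduced: np.ndarray, db, cutoff: float) -> list:
    """Representative ids whose reduced-signature Euclidean distance to the
    target is <= cutoff (math.inf disables the filter)."""
    if np.isinf(cutoff):
        return [t.rep_id for t in db.representatives]
    if db.reduced_matrix is None or db.svd_model is None:
        raise DimensionError("database has no fitted signature model")
    t = np.asarray(target_reduced, dtype=float).reshape(1, -1)
    if t.shape[1] != db.svd_model.k:
        raise DimensionError(f"reduced vector length {t.shape[1]} != model k {db.svd_model.k}")
    d = cdist(t, db.reduced_matrix)[0]
    return [db.representatives[i].rep_id for i in np.where(d <= cutoff)[0]]


def calibrate_lossless_cutoff(db, targets_reduced, true_ids_per_target) -> float:
    """Smallest signature-filter cutoff that loses no true match.

    ``targets_reduced`` is an iterable of reduced target vectors and
    ``true_ids_per_target`` the matching iterable of sets of representative
    ids confirmed by the RMSD search.  Returns the maximum reduced-signature
    distance between any target and any of its true matches (0.0 if there are
    none).
    """
    if db.reduced_matrix is None:
        raise DimensionError("database has no fitted signature model")
    pos = {t.rep_id: i for i, t in enumerate(db.representatives)}
    worst = 0.0
    for vec, ids in zip(targets_reduced, true_ids_per_target):
        vec = np.asarray(vec, dtype=float)
        for rid in ids:
            d = float(np.linalg.norm(vec - db.reduced_matrix[pos[rid]]))
            worst = max(worst, d)
    return worst


# --- persistence (plain text) ----------------------------------------------

def save_svd_model(model: SVDModel, directory) -> None:
    directory = Path(directory)
    meta = {"k": model.k, "energy_fraction": model.energy_fraction,
            "criterion": model.criterion,
            "singular_values": model.singular_values.tolist()}
    (directory / "svd_model.json").write_text(json.dumps(meta))
    np.savetxt(directory / "svd_basis.tsv", model.basis, delimiter="\t")


def load_svd_model(directory) -> SVDModel:
    directory = Path(directory)
    meta = json.loads((directory / "svd_model.json").read_text())
    basis = np.loadtxt(directory / "svd_basis.tsv", delimiter="\t", ndmin=2)
    return SVDModel(basis=basis, singular_values=np.asarray(meta["singular_values"]),
                    k=int(meta["k"]), energy_fraction=float(meta["energy_fraction"]),
                    criterion=meta["criterion"])
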