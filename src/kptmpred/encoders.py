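"""Sequence feature encoders for K-centered peptide windows.

Four encoders, each a scikit-learn transformer over a list of window
strings, plus an ensemble transformer that concatenates them serially
and standardizes the result:

- :class:`AAFEncoder` — five physicochemical factor scores per residue,
  5·(2ζ+1) columns;
- :class:`BinaryEncoder` — one-hot over the 21-letter alphabet,
  21·(2ζ+1) columns;
- :class:`CKSAAPEncoder` — composition of k-spaced amino-acid pairs,
  441 ordered-pair frequencies per spacing k;
- :class:`SequenceCouplingEncoder` — per-offset difference between the
  positive- and negative-class (conditional) probability of the observed
  residue, 2ζ columns.  This is the only encoder that learns from data.

For ζ=24 and k=0..4 the ensemble is 245 + 1029 + 2205 + 48 = 3527 columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler

from .aaf import AAF_MATRIX, N_FACTORS
from .alphabet import ALPHABET, ALPHABET_SIZE, windows_to_indices
from .dataset import DEFAULT_ZETA
from .errors import EmptyInputError, ShapeError, WindowTooShortError

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = (0, 1, 2, 3, 4)
DEFAULT_PSEUDOCOUNT = 1e-4


def _offsets(zeta: int) -> list[int]:
    """Non-center offsets in window order: -ζ..-1, +1..+ζ."""
    return [j for j in range(-zeta, zeta + 1) if j != 0]


def _check_windows(X, zeta: int) -> np.ndarray:
    idx = windows_to_indices(X)
    if idx.shape[0] and idx.shape[1] != 2 * zeta + 1:
        raise ShapeError(
            f"windows have length {idx.shape[1]}, expected 2ζ+1 = {2 * zeta + 1}")
    return idx


class AAFEncoder(BaseEstimator, TransformerMixin):
    """Amino-acid-factor encoding: 5 factor scores per residue.

    Position-major: columns run residue by residue, the five factors
    (polarity, secondary structure, molecular volume, codon diversity,
    charge) contiguous within each residue.  The wildcard 'Z' contributes
    an all-zero block.
    """

    def __init__(self, zeta: int = DEFAULT_ZETA):
        self.zeta = zeta

    def fit(self, X, y=None):
        _check_windows(X, self.zeta)
        self.n_features_out_ = N_FACTORS * (2 * self.zeta + 1)
        return self

    def transform(self, X) -> np.ndarray:
        idx = _check_windows(X, self.zeta)
        return AAF_MATRIX[idx].reshape(idx.shape[0], -1)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"aaf:{j:+d}:f{f + 1}"
                 for j in range(-self.zeta, self.zeta + 1)
                 for f in range(N_FACTORS)]
        return np.asarray(names, dtype=object)


class BinaryEncoder(BaseEstimator, TransformerMixin):
    """One-hot encoding over the 21-letter alphabet, position-major."""

    def __init__(self, zeta: int = DEFAULT_ZETA):
        self.zeta = zeta

    def fit(self, X, y=None):
        _check_windows(X, self.zeta)
        self.n_features_out_ = ALPHABET_SIZE * (2 * self.zeta + 1)
        return self

    def transform(self, X) -> np.ndarray:
        idx = _check_windows(X, self.zeta)
        n, width = idx.shape
        out = np.zeros((n, width * ALPHABET_SIZE), dtype=np.float64)
        cols = np.arange(width) * ALPHABET_SIZE + idx
        out[np.arange(n)[:, None], cols] = 1.0
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"be:{j:+d}:{aa}"
                 for j in range(-self.zeta, self.zeta + 1)
                 for aa in ALPHABET]
        return np.asarray(names, dtype=object)


class CKSAAPEncoder(BaseEstimator, TransformerMixin):
    """Composition of k-spaced amino-acid pairs.

    For each spacing k the 441 ordered pair counts (a, b) with b exactly
    k residues downstream of a are divided by the number of such pairs in
    the window, N_total(k) = (2ζ+1) − k − 1, so each 441-block sums to 1.
    Blocks are concatenated in ascending k.
    """

    def __init__(self, zeta: int = DEFAULT_ZETA,
                 k_values: Sequence[int] = DEFAULT_K_VALUES):
        self.zeta = zeta
        self.k_values = k_values

    def _validate_k(self):
        width = 2 * self.zeta + 1
        ks = list(self.k_values)
        if not ks:
            raise ValueError("k_values must be non-empty")
        if max(ks) > width - 2:
            raise WindowTooShortError(
                f"k={max(ks)} leaves no pairs in a window of length {width}")
        return ks, width

    def fit(self, X, y=None):
        ks, _ = self._validate_k()
        _check_windows(X, self.zeta)
        self.n_features_out_ = ALPHABET_SIZE ** 2 * len(ks)
        return self

    def transform(self, X) -> np.ndarray:
        ks, width = self._validate_k()
        idx = _check_windows(X, self.zeta)
        n = idx.shape[0]
        n_pair = ALPHABET_SIZE ** 2
        blocks = []
        row_base = np.arange(n)[:, None] * n_pair
        for k in ks:
            n_total = width - k - 1
            codes = idx[:, : n_total] * ALPHABET_SIZE + idx[:, k + 1:]
            counts = np.bincount((codes + row_base).ravel(),
                                 minlength=n * n_pair).reshape(n, n_pair)
            blocks.append(counts / float(n_total))
        return np.concatenate(blocks, axis=1)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"cksaap:k{k}:{a}{b}"
                 for k in self.k_values for a in ALPHABET for b in ALPHABET]
        return np.asarray(names, dtype=object)


@dataclass
class CouplingModel:
    """Position-specific probability tables for one class of windows.

    For offsets j = −ζ..−2 the table at j is the conditional
    p(residue a at j | residue b at j+1), i.e. each flank residue is
    conditioned on its neighbor one step toward the center; mirrored for
    j = +2..+ζ.  Offsets ±1 adjoin the invariant central K and carry
    unconditional position-specific marginals.  A pseudocount is added to
    every cell before normalization so no probability is exactly zero.

    ``tables[j]`` is a (21, 21) array (conditional, columns index the
    conditioning residue b, each column sums to 1) or a (21,) array
    (marginal) keyed by signed offset.
    """

    zeta: int
    pseudocount: float
    tables: dict[int, np.ndarray]

    @classmethod
    def fit(cls, windows: Sequence[str], zeta: int,
            pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "CouplingModel":
        if len(windows) == 0:
            raise EmptyInputError("cannot fit a coupling model on no windows")
        idx = _check_windows(windows, zeta)
        tables: dict[int, np.ndarray] = {}
        for j in _offsets(zeta):
            c = zeta + j
            if abs(j) == 1:
                counts = np.bincount(idx[:, c], minlength=ALPHABET_SIZE
                                     ).astype(np.float64) + pseudocount
                tables[j] = counts / counts.sum()
            else:
                nb = c + 1 if j < 0 else c - 1
                counts = np.zeros((ALPHABET_SIZE, ALPHABET_SIZE))
                np.add.at(counts, (idx[:, c], idx[:, nb]), 1.0)
                counts += pseudocount
                tables[j] = counts / counts.sum(axis=0, keepdims=True)
        return cls(zeta, pseudocount, tables)

    def probabilities(self, idx: np.ndarray) -> np.ndarray:
        """Per-offset probability of each window's observed residues.

        ``idx`` is an (n, 2ζ+1) index array; returns (n, 2ζ) in window
        offset order −ζ..−1, +1..+ζ.
        """
        n = idx.shape[0]
        offs = _offsets(self.zeta)
        out = np.empty((n, len(offs)))
        for col, j in enumerate(offs):
            c = self.zeta + j
            t = self.tables[j]
            if t.ndim == 1:
                out[:, col] = t[idx[:, c]]
            else:
                nb = c + 1 if j < 0 else c - 1
                out[:, col] = t[idx[:, c], idx[:, nb]]
        return out

    # -- JSON round-trip ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "alphabet": ALPHABET,
            "zeta": self.zeta,
            "pseudocount": self.pseudocount,
            "tables": {str(j): t.tolist() for j, t in self.tables.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CouplingModel":
        payload = json.loads(text)
        if payload["alphabet"] != ALPHABET:
            raise ValueError("coupling model was fitted on a different alphabet")
        tables = {int(j): np.asarray(t, dtype=np.float64)
                  for j, t in payload["tables"].items()}
        return cls(int(payload["zeta"]), float(payload["pseudocount"]), tables)


class SequenceCouplingEncoder(BaseEstimator, TransformerMixin):
    """Sequence-coupling encoding: positive-minus-negative probabilities.

    Fits one :class:`CouplingModel` on the positive training windows
    (y == 1) and one on the negatives (y == 0).  A window is then encoded,
    per non-center offset, as the positive-model probability of its
    observed residue minus the negative-model probability — 2ζ features,
    each in [−1, 1].  The central K is invariant and omitted.
    """

    def __init__(self, zeta: int = DEFAULT_ZETA,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.zeta = zeta
        self.pseudocount = pseudocount

    def fit(self, X, y):
        y = np.asarray(y)
        X = list(X)
        if len(X) != len(y):
            raise ShapeError(f"{len(X)} windows but {len(y)} labels")
        pos = [w for w, t in zip(X, y) if t == 1]
        neg = [w for w, t in zip(X, y) if t == 0]
        if not pos or not neg:
            raise EmptyInputError(
                "coupling fit needs non-empty positive and negative subsets")
        self.positive_model_ = CouplingModel.fit(pos, self.zeta, self.pseudocount)
        self.negative_model_ = CouplingModel.fit(neg, self.zeta, self.pseudocount)
        self.n_features_out_ = 2 * self.zeta
        return self

    def transform(self, X) -> np.ndarray:
        idx = _check_windows(X, self.zeta)
        return (self.positive_model_.probabilities(idx)
                - self.negative_model_.probabilities(idx))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"coupling:{j:+d}" for j in _offsets(self.zeta)],
                          dtype=object)


_ENCODER_ORDER = ("aaf", "be", "cksaap", "coupling")


class EnsembleEncoder(BaseEstimator, TransformerMixin):
    """Serial concatenation AAF ∥ BE ∥ CKSAAP ∥ coupling, standardized.

    The coupling sub-encoder and the per-column standardization are
    fitted on the training windows only (``fit`` requires the binary
    modified/unmodified label vector when coupling is enabled) and applied
    unchanged to any other subset, so no validation-fold information leaks
    into the representation.  Zero-variance columns keep scale 1 and are
    reported in a warning.
    """

    def __init__(self, zeta: int = DEFAULT_ZETA,
                 encoders: Sequence[str] = _ENCODER_ORDER,
                 k_values: Sequence[int] = DEFAULT_K_VALUES,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 standardize: bool = True):
        self.zeta = zeta
        self.encoders = encoders
        self.k_values = k_values
        self.pseudocount = pseudocount
        self.standardize = standardize

    def _make_encoders(self):
        unknown = set(self.encoders) - set(_ENCODER_ORDER)
        if unknown:
            raise ValueError(f"unknown encoder name(s) {sorted(unknown)}")
        made = []
        for name in _ENCODER_ORDER:  # serial order is fixed
            if name not in self.encoders:
                continue
            if name == "aaf":
                made.append((name, AAFEncoder(self.zeta)))
            elif name == "be":
                made.append((name, BinaryEncoder(self.zeta)))
            elif name == "cksaap":
                made.append((name, CKSAAPEncoder(self.zeta, self.k_values)))
            else:
                made.append((name, SequenceCouplingEncoder(
                    self.zeta, self.pseudocount)))
        if not made:
            raise ValueError("no encoders enabled")
        return made

    def fit(self, X, y=None):
        X = list(X)
        self.encoders_ = self._make_encoders()
        for name, enc in self.encoders_:
            if name == "coupling":
                if y is None:
                    raise ValueError(
                        "coupling encoder needs the binary labels at fit time")
                enc.fit(X, y)
            else:
                enc.fit(X)
        self.feature_names_out_ = np.concatenate(
            [enc.get_feature_names_out() for _, enc in self.encoders_])
        self.n_features_out_ = len(self.feature_names_out_)
        if self.standardize:
            raw = self._raw_transform(X)
            self.scaler_ = StandardScaler().fit(raw)
            n_const = int(np.sum(self.scaler_.var_ == 0))
            if n_const:
                logger.warning(
                    "%d zero-variance feature column(s); scale kept at 1",
                    n_const)
        return self

    def _raw_transform(self, X) -> np.ndarray:
        return np.concatenate([enc.transform(X) for _, enc in self.encoders_],
                              axis=1)

    def transform(self, X) -> np.ndarray:
        out = self._raw_transform(list(X))
        if self.standardize:
            out = self.scaler_.transform(out)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_out_


# ---------------------------------------------------------------------------
# Thin functional wrappers over the transformers

def encode_aaf(window: str, zeta: int | None = None) -> np.ndarray:
    """Encode one window with the amino-acid-factor scores (5·(2ζ+1))."""
    zeta = (len(window) - 1) // 2 if zeta is None else zeta
    return AAFEncoder(zeta).fit([window]).transform([window])[0]


def encode_binary(window: str, zeta: int | None = None) -> np.ndarray:
    """One-hot encode one window over the 21-letter alphabet (21·(2ζ+1))."""
    zeta = (len(window) - 1) // 2 if zeta is None else zeta
    return BinaryEncoder(zeta).fit([window]).transform([window])[0]


def encode_cksaap(window: str, k_values: Sequence[int] = DEFAULT_K_VALUES,
                  zeta: int | None = None) -> np.ndarray:
    """k-spaced pair frequencies for one window (441·|k_values|)."""
    zeta = (len(window) - 1) // 2 if zeta is None else zeta
    return CKSAAPEncoder(zeta, k_values).fit([window]).transform([window])[0]


def fit_coupling(positives: Sequence[str], negatives: Sequence[str],
                 zeta: int, pseudocount: float = DEFAULT_PSEUDOCOUNT
                 ) -> SequenceCouplingEncoder:
    """Fit the coupling encoder from explicit positive/negative windows."""
    windows = list(positives) + list(negatives)
    y = np.r_[np.ones(len(positives), dtype=int),
              np.zeros(len(negatives), dtype=int)]
    return SequenceCouplingEncoder(zeta, pseudocount).fit(windows, y)


def encode_coupling(window: str, encoder: SequenceCouplingEncoder) -> np.ndarray:
    """Coupling features (2ζ) for one window under a fitted encoder."""
    return encoder.transform([window])[0]


def encode_ensemble(windows, encoder: EnsembleEncoder) -> np.ndarray:
    """Apply a fitted ensemble encoder to a batch of windows."""
    return encoder.transform(list(windows))


def write_feature_tsv(X: np.ndarray, column_names, path) -> None:
    """Persist a feature matrix as TSV with a one-line header."""
    import pandas as pd

    pd.DataFrame(np.asarray(X), columns=list(column_names)).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_feature_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Load a feature matrix written by :func:`write_feature_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=np.float64), list(df.columns)
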