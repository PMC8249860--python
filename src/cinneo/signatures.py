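"""Mutational-signature refitting by forward-selected nonnegative least squares.

A sample's 96-context catalog, normalized to a probability vector p, is
modelled as a nonnegative linear combination of fixed reference signature
columns. Signatures enter one at a time: at each step every unused
signature is trial-fitted by exact NNLS together with the current set, the
one giving the largest drop in the sum of squared errors is added, and
selection stops once the relative SSE improvement falls below a tolerance.
Final exposures below a reporting cutoff (default 0.06, the conventional
discard threshold for refitting tools) are zeroed and the surviving set is
re-solved. Exposures are reported as fractions of the normalized catalog.

The model/results split follows the statsmodels idiom: build a
:class:`SignatureRefit` from data, call :meth:`~SignatureRefit.fit`, read
estimates and diagnostics off the returned :class:`SignatureRefitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectrum import CONTEXT_LABELS, MutationCatalog

__all__ = [
    "SignatureMatrix",
    "SignatureRefit",
    "SignatureRefitResults",
    "refit",
    "reconstruction",
    "cosine_similarity",
    "cohort_signature_summary",
]


class SignatureMatrix:
    """K named signature columns over the 96 trinucleotide contexts.

    Each column is a probability distribution (nonnegative, sums to 1);
    rows follow the catalog's class-major context ordering.
    """

    def __init__(self, profiles: pd.DataFrame):
        if list(profiles.index) != list(CONTEXT_LABELS):
            if len(profiles) != 96:
                raise ValueError(f"signature matrix has {len(profiles)} rows, need 96")
            profiles = profiles.reindex(CONTEXT_LABELS)
            if profiles.isna().any().any():
                raise ValueError("signature matrix row labels do not cover all 96 contexts")
        arr = profiles.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signature probabilities must be nonnegative")
        colsums = arr.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("every signature column must sum to 1")
        self.frame = profiles
        self.names = list(profiles.columns)
        self.values = arr  # (96, K)

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="context")

    def __len__(self):
        return len(self.names)


@dataclass
class SignatureRefitResults:
    """Estimated exposures and reconstruction diagnostics for one sample."""

    sample_id: str
    weights: dict            # signature name -> exposure fraction (>= cutoff)
    residual_sse: float
    n_mutations: int
    fitted: bool = True

    @property
    def unexplained(self) -> float:
        return max(0.0, 1.0 - sum(self.weights.values()))

    def reconstructed(self, signatures: "SignatureMatrix") -> np.ndarray:
        w = np.array([self.weights.get(n, 0.0) for n in signatures.names])
        return signatures.values @ w

    def summary(self) -> pd.DataFrame:
        rows = sorted(self.weights.items(), key=lambda kv: -kv[1])
        df = pd.DataFrame(rows, columns=["signature", "exposure"])
        df.attrs["sample_id"] = self.sample_id
        df.attrs["residual_sse"] = self.residual_sse
        df.attrs["unexplained"] = self.unexplained
        return df


class SignatureRefit:
    """Refitting model for one catalog against a fixed signature matrix.

    Parameters
    ----------
    catalog : MutationCatalog or array-like of 96 counts
    signatures : SignatureMatrix
    weight_cutoff : float
        Exposures below this fraction are zeroed after selection (0.06).
    improvement_tol : float
        Stop adding signatures when the relative SSE improvement of the
        best candidate falls below this (1e-3).
    """

    def __init__(
        self,
        catalog,
        signatures: SignatureMatrix,
        weight_cutoff: float = 0.06,
        improvement_tol: float = 1e-3,
    ):
        if isinstance(catalog, MutationCatalog):
            self.sample_id = catalog.sample_id
            counts = catalog.context96
        else:
            self.sample_id = ""
            counts = np.asarray(catalog, dtype=float)
        if counts.shape != (96,):
            raise ValueError("catalog must have 96 context counts")
        if (counts < 0).any():
            raise ValueError("catalog counts must be nonnegative")
        self.counts = np.asarray(counts, dtype=float)
        self.signatures = signatures
        self.weight_cutoff = float(weight_cutoff)
        self.improvement_tol = float(improvement_tol)

    def fit(self) -> SignatureRefitResults:
        n_mut = int(round(self.counts.sum()))
        if n_mut == 0:
            return SignatureRefitResults(
                sample_id=self.sample_id,
                weights={},
                residual_sse=float("nan"),
                n_mutations=0,
                fitted=False,
            )
        p = self.counts / self.counts.sum()
        S = self.signatures.values
        K = S.shape[1]

        selected: list = []
        sse_prev = float(p @ p)  # SSE of the empty model
        while len(selected) < K:
            best_j, best_sse = None, None
            for j in range(K):
                if j in selected:
                    continue
                _, rnorm = nnls(S[:, selected + [j]], p)
                sse = rnorm**2
                if best_sse is None or sse < best_sse - 1e-15:
                    best_j, best_sse = j, sse
            if sse_prev > 0 and (sse_prev - best_sse) / sse_prev < self.improvement_tol:
                break
            selected.append(best_j)
            sse_prev = best_sse
            if best_sse <= 1e-18:
                break

        w, rnorm = nnls(S[:, selected], p) if selected else (np.array([]), np.sqrt(sse_prev))
        # drop sub-cutoff exposures and re-solve on the survivors
        keep = [j for j, wj in zip(selected, w) if wj >= self.weight_cutoff]
        if keep != selected:
            if keep:
                w, rnorm = nnls(S[:, keep], p)
                selected = keep
            else:
                selected, w, rnorm = [], np.array([]), np.linalg.norm(p)
        total = w.sum()
        if total > 1.0:  # exposures are fractions of the catalog
            w = w / total
            rnorm = np.linalg.norm(S[:, selected] @ w - p) if selected else rnorm
        weights = {self.signatures.names[j]: float(wj) for j, wj in zip(selected, w)}
        return SignatureRefitResults(
            sample_id=self.sample_id,
            weights=weights,
            residual_sse=float(rnorm**2),
            n_mutations=n_mut,
        )


def refit(
    catalog,
    signatures: SignatureMatrix,
    weight_cutoff: float = 0.06,
    improvement_tol: float = 1e-3,
) -> SignatureRefitResults:
    """Functional one-shot wrapper around :class:`SignatureRefit`."""
    return SignatureRefit(catalog, signatures, weight_cutoff, improvement_tol).fit()


def reconstruction(weights: Mapping[str, float], signatures: SignatureMatrix) -> np.ndarray:
    w = np.array([weights.get(n, 0.0) for n in signatures.names])
    return signatures.values @ w


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def cohort_signature_summary(
    results: Sequence[SignatureRefitResults], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group mean exposure proportions (rows: group, cols: signature).

    Each fitted sample's exposures are renormalized to sum to 1 before
    averaging, so groups with different unexplained mass stay comparable;
    group rows are then renormalized means.
    """
    names = sorted({n for r in results for n in r.weights})
    per_group: dict = {}
    for r in results:
        if not r.fitted or not r.weights:
            continue
        g = groups[r.sample_id]
        total = sum(r.weights.values())
        vec = np.array([r.weights.get(n, 0.0) / total for n in names])
        per_group.setdefault(g, []).append(vec)
    rows = {}
    for g, vecs in per_group.items():
        mean = np.mean(vecs, axis=0)
        rows[g] = mean / mean.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=names).fillna(0.0)
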