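"""96-context mutation profiles and signature deconvolution.

A sample's retained substitutions are binned into the standard 96
trinucleotide contexts (six pyrimidine-strand substitution types x four
5' bases x four 3' bases; purine-reference variants are reverse
complemented).  The normalized profile is then refit against a pool of
COSMIC-style signature columns augmented with "background signatures" —
the profiles of selected control samples, which absorb platform noise
and clonal hematopoiesis.  With the signature matrix fixed, the
non-negative factorization reduces to non-negative least squares; we run
seeded multiplicative updates to convergence and polish with an exact
NNLS solve, so results are deterministic and tight.  The summed
contribution of the non-background (COSMIC) columns is the
tumor-associated score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import ReferenceGenome, revcomp
from .io import logger
from .variants import VariantCall

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = ("A", "C", "G", "T")

#: Canonical channel order: substitution-major, then 5' base, then 3' base.
CONTEXT_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _FLANKS
    for three in _FLANKS
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_96)}


def context_label(ref: str, alt: str, five: str, three: str) -> str:
    """96-channel label for a substitution with its flanking bases.

    Purine-reference variants are mapped to the pyrimidine strand by
    reverse complementing the whole trinucleotide.
    """
    if ref in "AG":
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class MutationProfile:
    """Normalized 96-context substitution profile of one sample."""

    sample_id: str
    counts: np.ndarray  # shape (96,), integer counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("counts must have shape (96,)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(96)
        return self.counts / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=list(CONTEXT_96), name=self.sample_id)


@dataclass
class SignaturePool:
    """96 x K matrix of signature columns, each summing to one."""

    matrix: np.ndarray
    names: list[str]
    is_background: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_artifact: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("matrix must be 96 x K")
        k = self.matrix.shape[1]
        if len(self.names) != k:
            raise ValueError("one name per column required")
        if k < 1:
            raise ValueError("pool must contain at least one signature")
        if self.is_background is None:
            self.is_background = np.zeros(k, dtype=bool)
        if self.is_artifact is None:
            self.is_artifact = np.zeros(k, dtype=bool)
        self.is_background = np.asarray(self.is_background, dtype=bool)
        self.is_artifact = np.asarray(self.is_artifact, dtype=bool)
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("every signature column must sum to 1 (±1e-8)")
        if (self.matrix < 0).any():
            raise ValueError("signature columns must be non-negative")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def without_artifacts(self) -> "SignaturePool":
        """Drop artifact-flagged columns before fitting."""
        keep = ~self.is_artifact
        return SignaturePool(
            self.matrix[:, keep],
            [n for n, k in zip(self.names, keep) if k],
            self.is_background[keep],
            np.zeros(int(keep.sum()), dtype=bool),
        )

    def with_background(self, columns: np.ndarray, names: Sequence[str]) -> "SignaturePool":
        """Return a new pool with background columns appended."""
        columns = np.asarray(columns, dtype=float)
        if columns.ndim == 1:
            columns = columns[:, None]
        return SignaturePool(
            np.hstack([self.matrix, columns]),
            list(self.names) + list(names),
            np.concatenate([self.is_background, np.ones(columns.shape[1], dtype=bool)]),
            np.concatenate([self.is_artifact, np.zeros(columns.shape[1], dtype=bool)]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CONTEXT_96), columns=self.names)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        background_names: Iterable[str] = (),
        artifact_names: Iterable[str] = (),
    ) -> "SignaturePool":
        """Read a COSMIC-layout TSV: 96 labelled rows, one column per signature."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CONTEXT_96) - set(frame.index)
        if missing:
            raise ValueError(f"{path}: missing context rows, e.g. {sorted(missing)[:3]}")
        frame = frame.loc[list(CONTEXT_96)]
        background = set(background_names)
        artifact = set(artifact_names)
        names = [str(c) for c in frame.columns]
        return cls(
            frame.to_numpy(dtype=float),
            names,
            np.array([n in background for n in names]),
            np.array([n in artifact for n in names]),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="MutationType")


@dataclass
class DeconvolutionResult:
    """Relative signature contributions for one profile."""

    contributions: np.ndarray  # K non-negative reals summing to 1
    names: list[str]
    is_background: np.ndarray
    cosine: float
    n_iterations: int = 0

    @property
    def cosmic_total(self) -> float:
        """Summed contribution of non-background (tumor-associated) columns."""
        return float(self.contributions[~self.is_background].sum())

    @property
    def background_total(self) -> float:
        return float(self.contributions[self.is_background].sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.contributions, index=self.names)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profile(
    calls: Sequence[VariantCall],
    reference: ReferenceGenome,
    sample_id: str = "sample",
) -> MutationProfile:
    """Bin retained substitutions into the 96 trinucleotide channels.

    Calls whose trinucleotide context contains N (or sits at a contig
    edge) are skipped with a logged count.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for call in calls:
        if not call.is_snv:
            raise ValueError(f"not a substitution: {call.ref}>{call.alt}")
        pos0 = call.pos - 1
        chrom_len = reference.chrom_length(call.chrom)
        if pos0 < 1 or pos0 + 1 >= chrom_len:
            skipped += 1
            continue
        tri = reference.fetch(call.chrom, pos0 - 1, pos0 + 2)
        if "N" in tri:
            skipped += 1
            continue
        if tri[1] != call.ref:
            raise ValueError(
                f"reference mismatch at {call.chrom}:{call.pos}: "
                f"call says {call.ref}, genome says {tri[1]}"
            )
        label = context_label(call.ref, call.alt, tri[0], tri[2])
        counts[_CONTEXT_INDEX[label]] += 1
    if skipped:
        logger.warning("build_profile(%s): skipped %d calls with N/edge context",
                       sample_id, skipped)
    return MutationProfile(sample_id, counts)


def build_background(
    control_profiles: Sequence[MutationProfile],
    n_select: int,
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    """Pick ``n_select`` control profiles (seeded, without replacement) to
    serve as background signature columns.

    Controls with zero variants are ineligible.  Returns the 96 x n
    column block and the control sample ids.
    """
    eligible = [p for p in control_profiles if p.total > 0]
    if n_select > len(eligible):
        raise ValueError(
            f"n_select={n_select} exceeds {len(eligible)} eligible controls"
        )
    if n_select == 0:
        return np.zeros((96, 0)), []
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(eligible), size=n_select, replace=False))
    chosen = [eligible[i] for i in idx]
    block = np.column_stack([p.frequencies for p in chosen])
    return block, [p.sample_id for p in chosen]


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def deconvolute(
    profile: MutationProfile,
    pool: SignaturePool,
    seed: int = 0,
    max_iter: int = 10_000,
    rel_tol: float = 1e-8,
) -> DeconvolutionResult:
    """Refit a profile against a fixed signature pool.

    Artifact columns are removed before fitting.  Weights start from a
    seeded random point, run multiplicative updates (the classic NMF
    update with the basis fixed) until the relative error change drops
    below ``rel_tol``, then are polished with an exact NNLS solve; the
    better of the two solutions is kept and renormalized to sum to one.
    """
    if profile.total == 0:
        raise ValueError("cannot deconvolute an empty profile")
    pool = pool.without_artifacts()
    v = profile.frequencies
    w = pool.matrix  # 96 x K

    rank = np.linalg.matrix_rank(w)
    if rank < pool.k:
        logger.warning("signature pool is rank-deficient (rank %d < %d columns)",
                       rank, pool.k)

    rng = np.random.default_rng(seed)
    h = rng.uniform(0.1, 1.0, size=pool.k)
    wt_v = w.T @ v
    wt_w = w.T @ w
    prev_err = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        denom = wt_w @ h
        h *= wt_v / np.maximum(denom, 1e-300)
        err = float(np.linalg.norm(v - w @ h))
        if prev_err - err < rel_tol * max(prev_err, 1e-300):
            break
        prev_err = err

    h_nnls, _ = nnls(w, v)
    if np.linalg.norm(v - w @ h_nnls) <= np.linalg.norm(v - w @ h):
        h = h_nnls

    total = h.sum()
    contributions = h / total if total > 0 else h
    recon = w @ h
    return DeconvolutionResult(
        contributions=contributions,
        names=list(pool.names),
        is_background=pool.is_background.copy(),
        cosine=_cosine(v, recon),
        n_iterations=n_iter,
    )


def profile_table(profiles: Sequence[MutationProfile]) -> pd.DataFrame:
    """Samples x 96 frequency table (feature-matrix block)."""
    return pd.DataFrame(
        [p.frequencies for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=list(CONTEXT_96),
    )
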