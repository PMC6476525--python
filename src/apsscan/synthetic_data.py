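"""Seeded generators emulating every input the analysis stages consume.

Transcripts with controlled per-region AU composition and embedded conserved
blocks, Ct tables under a log2 expression model with Gaussian cycle noise,
log-normal luminescence batches, multinomial polysome fraction counts with a
tunable heavy-polysome tilt, and western band intensities — all pure functions
of (parameters, seed), so every pipeline stage is testable offline and
parameter recovery is measurable.

One global seed governs a named substream per generator (via
:func:`numpy.random.SeedSequence` spawning keyed on the generator name), so
adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polysome import FractionProfile, N_FRACTIONS, normalize_fractions
from .sequence_model import Region, Transcript, TranscriptError

__all__ = [
    "TranscriptRecipe",
    "NoiseModel",
    "gen_transcript",
    "gen_homolog_set",
    "gen_ct_table",
    "gen_luminescence",
    "gen_polysome",
    "gen_bands",
]

_STOPS = ("TAA", "TAG", "TGA")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """A named substream of the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(stream.encode()),))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class TranscriptRecipe:
    """Parameters for one synthetic transcript with controlled composition."""

    seed: int
    utr5_len: int = 150
    cds_len: int = 300
    utr3_len: int = 400
    au_utr5: float = 0.45
    au_cds: float = 0.50
    au_utr3: float = 0.60
    # (length nt, target AU fraction) for the 3'-UTR head, overriding au_utr3
    proximal_au_override: tuple[int, float] | None = None
    # (start 1-based within the 3' UTR, length nt) of a block kept mutation-free
    conserved_block: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.cds_len % 3 != 0 or self.cds_len < 6:
            raise TranscriptError(f"cds_len {self.cds_len} must be a multiple of 3 and >= 6")
        for label, au in (("au_utr5", self.au_utr5), ("au_cds", self.au_cds),
                          ("au_utr3", self.au_utr3)):
            if not (0.0 <= au <= 1.0):
                raise TranscriptError(f"{label}={au} outside [0, 1]")
        if self.proximal_au_override is not None:
            length, au = self.proximal_au_override
            if length > self.utr3_len:
                raise TranscriptError("proximal override longer than the 3' UTR")
            if not (0.0 <= au <= 1.0):
                raise TranscriptError(f"override AU {au} outside [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the quantification generators."""

    ct_sigma: float = 0.2  # cycles, Gaussian on the Ct scale
    lum_cv: float = 0.10  # coefficient of variation, log-normal multiplicative
    polysome_depth: int = 10_000  # total multinomial count per profile
    band_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.ct_sigma < 0 or self.lum_cv < 0 or self.band_cv < 0 or self.polysome_depth <= 0:
            raise TranscriptError("noise parameters must be positive")


def _draw_bases(rng: np.random.Generator, n: int, au: float) -> str:
    probs = [au / 2, (1 - au) / 2, (1 - au) / 2, au / 2]  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)]) if n else ""


def gen_transcript(recipe: TranscriptRecipe, *, id: str = "synthetic", gene: str = "SYN",
                   species: str = "synthetic") -> Transcript:
    """Draw one transcript with i.i.d. bases at per-region AU targets.

    Within each region P(A) = P(T) = au/2 and P(C) = P(G) = (1-au)/2.  The CDS
    begins with ATG and ends with a stop codon; an optional proximal override
    re-draws the first bases of the 3' UTR at their own AU target, which is
    how APS-positive and APS-negative UTRs are constructed to order.
    """
    rng = _rng(recipe.seed, "transcript")
    utr5 = _draw_bases(rng, recipe.utr5_len, recipe.au_utr5)
    body = _draw_bases(rng, recipe.cds_len - 6, recipe.au_cds)
    cds = "ATG" + body + _STOPS[int(rng.integers(len(_STOPS)))]
    utr3 = _draw_bases(rng, recipe.utr3_len, recipe.au_utr3)
    if recipe.proximal_au_override is not None:
        length, au = recipe.proximal_au_override
        utr3 = _draw_bases(rng, length, au) + utr3[length:]
    seq = utr5 + cds + utr3
    return Transcript(id, gene, species, seq,
                      cds_start=recipe.utr5_len + 1,
                      cds_end=recipe.utr5_len + recipe.cds_len)


def gen_homolog_set(
    reference: Region | str,
    n_species: int,
    substitution_rate: float,
    conserved_block: tuple[int, int] | None = None,
    *,
    seed: int = 0,
) -> list[Region]:
    """Simulate homologs of a reference region by i.i.d. substitution.

    Each homolog carries substitutions at ``substitution_rate`` outside the
    conserved block (1-based ``(start, length)``) and none inside it — the
    fixture for conserved-block recovery experiments.
    """
    ref = reference.seq if isinstance(reference, Region) else str(reference)
    if not (0.0 <= substitution_rate <= 0.5):
        raise TranscriptError(f"substitution rate {substitution_rate} outside [0, 0.5]")
    protected = np.zeros(len(ref), dtype=bool)
    if conserved_block is not None:
        start, length = conserved_block
        if not (1 <= start and start + length - 1 <= len(ref)):
            raise TranscriptError(
                f"conserved block [{start}, {start + length - 1}] outside reference "
                f"of length {len(ref)}"
            )
        protected[start - 1 : start + length - 1] = True
    rng = _rng(seed, "homologs")
    alphabet = "ACGT"
    homologs = []
    for k in range(n_species):
        bases = list(ref)
        hit = (rng.random(len(ref)) < substitution_rate) & ~protected
        for i in np.flatnonzero(hit):
            choices = [b for b in alphabet if b != bases[i]]
            bases[i] = choices[int(rng.integers(3))]
        homologs.append(Region(f"homolog_{k + 1}", "custom", 1, len(ref), "".join(bases)))
    return homologs


def gen_ct_table(
    true_folds: Mapping[str, float],
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    *,
    seed: int = 0,
    baseline_ct: float = 20.0,
    target: str = "TARGET",
    reference: str = "REF",
    control_sample: str = "control",
) -> pd.DataFrame:
    """Simulate a tidy Ct table under a log2 expression model.

    The reference gene sits at ``baseline_ct`` in every sample; the target
    gene's Ct is ``baseline - log2(fold)`` plus Gaussian noise of ``ct_sigma``
    cycles, so the 2^-ddCt method recovers ``true_folds`` exactly at zero
    noise.  The control sample (fold 1) is appended automatically.
    """
    rng = _rng(seed, "ct")
    folds = dict(true_folds)
    folds.setdefault(control_sample, 1.0)
    rows = []
    for sample, fold in folds.items():
        if fold <= 0:
            raise TranscriptError(f"true fold for {sample!r} must be positive")
        for rep in range(1, n_replicates + 1):
            rows.append({"sample": sample, "condition": sample, "gene": reference,
                         "replicate": rep,
                         "ct": baseline_ct + rng.normal(0, noise.ct_sigma)})
            rows.append({"sample": sample, "condition": sample, "gene": target,
                         "replicate": rep,
                         "ct": baseline_ct - np.log2(fold) + rng.normal(0, noise.ct_sigma)})
    return pd.DataFrame(rows)


def gen_luminescence(
    true_ratio: float,
    noise: NoiseModel = NoiseModel(),
    n: int = 6,
    *,
    seed: int = 0,
    control_level: float = 1000.0,
) -> pd.DataFrame:
    """Simulate paired UTR-reporter / control-reporter luminescence batches.

    Signals are log-normal around their expected level with coefficient of
    variation ``lum_cv``; the log-scale draw has zero mean, so per-replicate
    log2 ratios are unbiased estimates of ``log2(true_ratio)``.
    """
    if true_ratio <= 0:
        raise TranscriptError("true ratio must be positive")
    rng = _rng(seed, "luminescence")
    sigma = float(np.sqrt(np.log1p(noise.lum_cv**2)))
    ctrl = control_level * np.exp(rng.normal(0, sigma, size=n))
    utr = control_level * true_ratio * np.exp(rng.normal(0, sigma, size=n))
    return pd.DataFrame({
        "replicate": np.arange(1, n + 1),
        "utr_signal": utr,
        "control_signal": ctrl,
    })


def gen_polysome(
    mean_profile: Sequence[float],
    shift: float = 0.0,
    depth: int | None = None,
    *,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    mrna: str = "mrna",
    condition: str = "condition",
) -> FractionProfile:
    """Draw multinomial fraction counts around a tilted mean profile.

    ``shift`` is a per-fraction logit offset growing linearly with fraction
    index: sampling weights are ``p_i * exp(shift * (i - 1))`` renormalized,
    so positive shifts push mass toward the heavy (high-index) fractions —
    the qualitative signature of increased translation.
    """
    p = np.asarray(mean_profile, dtype=float).ravel()
    if p.size != N_FRACTIONS:
        raise TranscriptError(f"mean profile must have {N_FRACTIONS} fractions, got {p.size}")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise TranscriptError("mean profile must be non-negative and sum to 1")
    w = p * np.exp(shift * np.arange(p.size))
    w = w / w.sum()
    rng = _rng(seed, "polysome")
    counts = rng.multinomial(depth if depth is not None else noise.polysome_depth, w)
    return normalize_fractions(counts, mrna=mrna, condition=condition, n_fractions=p.size)


def tilted_profile(mean_profile: Sequence[float], shift: float) -> np.ndarray:
    """Closed-form expected fraction probabilities after the logit tilt."""
    p = np.asarray(mean_profile, dtype=float).ravel()
    w = p * np.exp(shift * np.arange(p.size))
    return w / w.sum()


def gen_bands(
    true_ratios: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    *,
    seed: int = 0,
    total_level: float = 100.0,
    background: float = 5.0,
) -> pd.DataFrame:
    """Simulate western band intensities with per-lane phospho/total ratios.

    Each lane gets a total band around ``total_level`` and a phospho band at
    ``ratio * total``; both carry log-normal multiplicative noise of CV
    ``band_cv`` and a shared additive per-lane background, so minimum-profile
    subtraction recovers the true ratios at zero noise.
    """
    rng = _rng(seed, "bands")
    sigma = float(np.sqrt(np.log1p(noise.band_cv**2))) if noise.band_cv > 0 else 0.0
    rows = []
    for i, ratio in enumerate(true_ratios):
        if ratio < 0:
            raise TranscriptError("band ratios must be non-negative")
        total = total_level * np.exp(rng.normal(0, sigma)) if sigma else total_level
        phospho = ratio * total_level * np.exp(rng.normal(0, sigma)) if sigma \
            else ratio * total_level
        rows.append({"lane": f"lane_{i + 1}",
                     "phospho_raw": phospho + background,
                     "total_raw": total + background,
                     "background": background})
    return pd.DataFrame(rows)
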