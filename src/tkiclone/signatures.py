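"""96-channel single-base-substitution spectra and signature decomposition.

Acquired SNVs of a subline are binned into the 96 pyrimidine-centred
trinucleotide channels (6 substitution types x 16 flank combinations) and
the resulting spectrum is decomposed against a reference signature matrix
by non-negative least squares:

    minimise || S x - p ||_2   subject to  x >= 0,

where p is the spectrum normalised to sum 1 and S is the 96 x k signature
matrix. Exposures are reported as x / sum(x).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import UndefinedFitError
from .model import VariantCall, VariantKey

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: Canonical channel order: substitution-major, then 5' flank, then 3' flank.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_label(triplet: str, alt: str) -> str:
    """Build a channel label from a pyrimidine-centred reference triplet and alt base."""
    return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"


def parse_channel(label: str) -> tuple[str, str]:
    """Inverse of :func:`channel_label` → (reference triplet, alt base)."""
    return label[0] + label[2] + label[6], label[4]


def context_of(call: VariantCall, reference: Mapping[str, str]) -> str | None:
    """Trinucleotide channel of an SNV, strand-normalised to a pyrimidine centre.

    Returns None (with a warning) when the variant is not an SNV, lacks a
    flanking base at a contig end, or disagrees with the reference base.
    """
    if not call.is_snv:
        return None
    seq = reference[call.chrom]
    i = call.pos - 1  # to 0-based
    if i < 1 or i >= len(seq) - 1:
        logger.warning("variant %s:%d lacks a flanking base; excluded", call.chrom, call.pos)
        return None
    triplet = seq[i - 1 : i + 2].upper()
    if triplet[1] != call.ref:
        logger.warning(
            "reference base mismatch at %s:%d (ref %s, sequence %s); excluded",
            call.chrom, call.pos, call.ref, triplet[1],
        )
        return None
    alt = call.alt
    if triplet[1] in "AG":  # purine centre: flip to the pyrimidine strand
        triplet = revcomp(triplet)
        alt = revcomp(alt)
    return channel_label(triplet, alt)


def spectrum(
    calls: Iterable[VariantCall],
    reference: Mapping[str, str],
    keys: set[VariantKey] | None = None,
) -> pd.Series:
    """96-channel SNV count spectrum over ``calls`` (restricted to ``keys`` if given).

    Indels and un-resolvable contexts are skipped; an empty selection yields
    an all-zero spectrum.
    """
    counts = pd.Series(0, index=list(CHANNELS_96), dtype=int)
    for call in calls:
        if keys is not None and call.key not in keys:
            continue
        channel = context_of(call, reference)
        if channel is not None:
            counts[channel] += 1
    counts.name = "count"
    return counts


@dataclass
class ExposureVector:
    """Non-negative signature exposures of one spectrum, normalised to sum 1."""

    exposures: pd.Series  # index: signature ids
    residual: float  # Frobenius norm of the fit residual on the normalised scale
    dominant: str
    dominant_tied: bool = False


def fit_exposures(spec: pd.Series, signatures: pd.DataFrame) -> ExposureVector:
    """NNLS decomposition of a 96-channel spectrum against a signature matrix.

    ``signatures`` is 96 x k with columns summing to 1 (as produced by
    :func:`tkiclone.io.read_signature_matrix`).
    """
    n_snvs = int(spec.sum())
    if n_snvs == 0:
        raise UndefinedFitError("cannot fit exposures to an empty spectrum")
    S = signatures.reindex(list(CHANNELS_96)).to_numpy(dtype=float)
    if np.isnan(S).any():
        raise UndefinedFitError("signature matrix does not cover all 96 channels")
    # Collinear duplicate columns make the solution non-unique but not invalid.
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn("signature matrix is rank-deficient; exposures may be non-unique")
    p = spec.reindex(list(CHANNELS_96)).to_numpy(dtype=float)
    p = p / p.sum()
    x, rnorm = nnls(S, p)
    total = x.sum()
    if total == 0:
        raise UndefinedFitError("NNLS returned the zero vector")
    exposures = pd.Series(x / total, index=signatures.columns, name="exposure")
    top = exposures.max()
    winners = sorted(exposures.index[exposures == top])
    tied = len(winners) > 1
    if tied:
        warnings.warn(f"dominant signature tied between {winners}; reporting {winners[0]}")
    return ExposureVector(
        exposures=exposures, residual=float(rnorm), dominant=winners[0], dominant_tied=tied
    )
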