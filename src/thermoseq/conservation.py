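"""Evolutionary conservation filters for binding sites.

Given a gap-aware multiple alignment of orthologous CRM sequences
(reference species first), a site annotated on the reference is mapped to
its alignment columns and re-scored in each other species with the same
PWM, strand and LLR threshold.  The strict filter keeps a site only if it
is above threshold in all of the first n species; the turnover-tolerant
filter keeps it if it is above threshold in at least m of n species,
allowing lineage-specific losses of deeply conserved sites.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .motifs import PWM, BindingSite, llr_score

_ACGT = set("ACGT")


def _ref_columns(ref_aligned: str) -> np.ndarray:
    """Map reference (ungapped) positions to alignment column indices."""
    return np.array([i for i, c in enumerate(ref_aligned) if c != "-"],
                    dtype=np.int64)


def site_conservation(alignment: Sequence[tuple], sites: Sequence[BindingSite],
                      pwms: dict, threshold_frac: float = 0.4) -> np.ndarray:
    """Boolean matrix (n_sites, n_species): site above threshold in species.

    alignment: list of (species_name, aligned_seq), reference first; all
    aligned sequences must share length.  A window that is gapped, runs off
    the alignment, or contains non-ACGT letters counts as non-conserved.
    The reference species column is True by construction.
    """
    if not alignment:
        raise ValueError("alignment lacks a reference sequence")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    ref_cols = _ref_columns(alignment[0][1])
    out = np.zeros((len(sites), len(alignment)), dtype=bool)
    for si, site in enumerate(sites):
        pwm: PWM = pwms[site.tf]
        if site.start + site.length > len(ref_cols):
            raise ValueError(f"site at {site.start} outside reference")
        cols = ref_cols[site.start:site.start + site.length]
        span = int(cols[-1]) - int(cols[0]) + 1
        out[si, 0] = True
        if span != site.length:
            continue                    # reference window itself is gapped
        cutoff = threshold_frac * pwm.llr_max
        for sp in range(1, len(alignment)):
            word = alignment[sp][1][cols[0]:cols[-1] + 1].upper()
            if set(word) <= _ACGT and \
                    llr_score(pwm, word, site.strand) > cutoff:
                out[si, sp] = True
    return out


def filter_strict(alignment, sites, pwms, n_species: int,
                  threshold_frac: float = 0.4) -> list:
    """Keep reference sites conserved in all of the first n_species species."""
    if n_species < 1 or n_species > len(alignment):
        raise ValueError(f"n_species={n_species} outside 1..{len(alignment)}")
    if n_species == 1:
        return list(sites)
    cons = site_conservation(alignment, sites, pwms, threshold_frac)
    keep = cons[:, :n_species].all(axis=1)
    return [s for s, k in zip(sites, keep) if k]


def filter_turnover(alignment, sites, pwms, n_species: int,
                    min_species: int | None = None,
                    threshold_frac: float = 0.4) -> list:
    """Keep sites conserved in >= min_species of the first n_species.

    Default min_species = ceil(n_species/2) + 1 (capped at n_species); the
    reference itself counts.  min_species = n_species reduces to
    filter_strict.
    """
    if n_species < 1 or n_species > len(alignment):
        raise ValueError(f"n_species={n_species} outside 1..{len(alignment)}")
    if min_species is None:
        min_species = min(n_species, math.ceil(n_species / 2) + 1)
    if not 1 <= min_species <= n_species:
        raise ValueError("min_species must be in 1..n_species")
    cons = site_conservation(alignment, sites, pwms, threshold_frac)
    keep = cons[:, :n_species].sum(axis=1) >= min_species
    return [s for s, k in zip(sites, keep) if k]
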