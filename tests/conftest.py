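"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from thermoseq.harness import random_instance, random_srr_instance  # noqa: F401
from thermoseq.motifs import BindingSite


def make_site(tf, start, length=6, strand="+", llr=0.0, llr_max=0.0):
    return BindingSite(tf=tf, start=start, length=length, strand=strand,
                       llr=llr, llr_max=llr_max)


def rel_err(a, b):
    return abs(a - b) / max(1e-300, abs(b))


def max_rel_err(r1, r2):
    return max(rel_err(r1.z_on, r2.z_on), rel_err(r1.z_off, r2.z_off),
               rel_err(r1.expression, r2.expression))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
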