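"""Synthetic reference signature set (COSMIC v2 stand-in).

The published COSMIC v2 probability matrix cannot be redistributed here, so
this module constructs a synthetic 30-signature reference whose key members
mimic the qualitative structure of the processes the real signatures are
named for: an ageing-like C>T-at-CpG profile (id 1), the two APOBEC
profiles concentrated at TpC (ids 2 and 13), a broad featureless
HRD/BRCA-like profile (id 3), a mismatch-repair-deficiency-like C>T profile
(id 6), and a POLE-like C>A-at-TpCpT profile (id 10).  The remaining ids
are sparse random profiles drawn once from a fixed seed.  Every profile is
a probability vector over the 96 contexts.

The reference is deterministic: the same matrix is produced on every call.
"""

from __future__ import annotations

import numpy as np

from .catalog import BASES, CONTEXT_96
from .signatures import SignatureMatrix

_REFERENCE_SEED = 746_113  # fixed; the reference is a constant of the package

#: Conventional aetiology names for the ids the matcher promotes to labels.
SIGNATURE_ALIASES = {
    "COSMIC 1": "CpG",
    "COSMIC 2": "APOBEC",
    "COSMIC 3": "BRCA",
    "COSMIC 6": "MSI",
    "COSMIC 10": "POLE",
    "COSMIC 13": "APOBEC",
}

#: Reference pairs reported jointly when they are the two best matches.
MERGED_PAIRS = (("COSMIC 2", "COSMIC 13"),)


def _peaked(weights: dict[str, float]) -> np.ndarray:
    """Profile with stated mass on named contexts plus a tiny flat floor."""
    v = np.full(96, 1e-3)
    for ctx, w in weights.items():
        v[CONTEXT_96.index(ctx)] += w
    return v / v.sum()


def _cpg_like() -> np.ndarray:
    # C>T at NpCpG, the deamination-of-methylcytosine pattern
    return _peaked({f"{b}[C>T]G": 1.0 for b in BASES})


def _apobec_like(alt: str) -> np.ndarray:
    # TpC focus; the pair's members are dominated by C>T and C>G
    # respectively but share a minor fraction of the other substitution,
    # as the deaminase process produces both outcomes
    other = "G" if alt == "T" else "T"
    w = {f"T[C>{alt}]{b}": 0.75 for b in BASES}
    w.update({f"T[C>{other}]{b}": 0.25 for b in BASES})
    return _peaked(w)


def _flat_brca_like(rng: np.random.Generator) -> np.ndarray:
    # near-uniform across all 96 channels with mild roughness
    v = rng.dirichlet(np.full(96, 50.0))
    return v / v.sum()


def _msi_like() -> np.ndarray:
    # C>T away from CpG, plus some T>C: crude mismatch-repair flavour
    w = {f"{b}[C>T]{b2}": 1.0 for b in ("C", "G") for b2 in ("A", "C", "T")}
    w.update({f"A[T>C]{b}": 0.6 for b in BASES})
    return _peaked(w)


def _pole_like() -> np.ndarray:
    return _peaked({"T[C>A]T": 3.0, "T[C>T]G": 1.0})


def synthetic_reference_signatures(n_signatures: int = 30) -> SignatureMatrix:
    """Build the synthetic 30-profile reference matrix.

    Ids are named "COSMIC 1" .. "COSMIC 30" so downstream labelling follows
    the field's naming convention, but the profiles themselves are
    synthetic constructs (see module docstring).
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    profiles: dict[int, np.ndarray] = {
        1: _cpg_like(),
        2: _apobec_like("T"),
        3: _flat_brca_like(rng),
        6: _msi_like(),
        10: _pole_like(),
        13: _apobec_like("G"),
    }
    for i in range(1, n_signatures + 1):
        if i not in profiles:
            # sparse random profile: mass on ~8 of 96 channels
            v = rng.dirichlet(np.full(96, 0.08))
            profiles[i] = v / v.sum()
    names = [f"COSMIC {i}" for i in range(1, n_signatures + 1)]
    mat = np.vstack([profiles[i] for i in range(1, n_signatures + 1)])
    return SignatureMatrix(names=names, profiles=mat)
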