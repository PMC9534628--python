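"""Descriptor encoders mapping a PSSM profile to fixed-length vectors.

Three descriptors are provided:

* **F-PSSM** (400-d) — after replacing negative scores with zero, the
  20 x 20 residue-type composition matrix ``M[a, j]`` holding the
  length-normalised sum of column-j scores over all positions whose
  sequence residue is amino acid ``a``, flattened row-major.
* **PSSM-DPC** (400-d) — dipeptide-composition-style products of
  consecutive-position score rows:
  ``D[i, j] = (1/L) * sum_k scores[k, i] * scores[k+1, j]``.
* **R-PSSM** (110-d) — built on a reduced 10-letter alphabet obtained
  by averaging physicochemically similar PSSM columns; 100
  pseudo-dipeptide squared-difference terms plus 10 per-column
  dispersion terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

from dbp_idwt.io_profiles import AA_ORDER, PssmProfile

#: Reduced-alphabet grouping: physicochemically similar residues share a
#: group; each reduced column is the mean of its source PSSM columns.
REDUCED_GROUPS: tuple[tuple[str, str], ...] = (
    ("G1", "FYW"),
    ("G2", "ML"),
    ("G3", "IV"),
    ("G4", "ATS"),
    ("G5", "NH"),
    ("G6", "QED"),
    ("G7", "RK"),
    ("G8", "C"),
    ("G9", "G"),
    ("G10", "P"),
)

#: Contracted output length per descriptor name.
DESCRIPTOR_LENGTHS = {
    "F-PSSM": 400,
    "PSSM-DPC": 400,
    "R-PSSM": 110,
    "F-PSSM-DWT": 512,
    "PSSM-DPC-DWT": 512,
    "R-PSSM-DWT": 512,
}


@dataclass
class ReducedProfile:
    """The L x 10 reduced-alphabet profile RP."""

    values: np.ndarray
    group_order: tuple[str, ...] = tuple(g for g, _ in REDUCED_GROUPS)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 10:
            raise ValueError(f"ReducedProfile must be L x 10, got {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """A named fixed-length descriptor for one protein."""

    descriptor_name: str
    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = DESCRIPTOR_LENGTHS.get(self.descriptor_name)
        if expected is not None and self.values.size != expected:
            raise ValueError(
                f"{self.descriptor_name} must have length {expected}, "
                f"got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.descriptor_name}: non-finite entries")


def filter_negative(profile: PssmProfile) -> PssmProfile:
    """Replace every negative score with zero (idempotent)."""
    return replace(profile, scores=np.maximum(profile.scores, 0.0))


def _require_min_length(profile_length: int, who: str) -> None:
    if profile_length < 2:
        raise ValueError(f"{who} needs L >= 2, got L = {profile_length}")


def encode_fpssm(profile: PssmProfile) -> FeatureVector:
    """Filtered-PSSM descriptor (400-d).

    Positions whose sequence residue is not one of the 20 standard
    letters contribute to no composition row and are skipped.
    """
    _require_min_length(profile.length, "F-PSSM")
    filtered = filter_negative(profile)
    comp = np.zeros((20, 20))
    for residue, row in zip(filtered.sequence, filtered.scores):
        idx = AA_ORDER.find(residue)
        if idx >= 0:
            comp[idx] += row
    comp /= profile.length
    return FeatureVector("F-PSSM", comp.ravel(), profile.protein_id)


def encode_pssm_dpc(
    profile: PssmProfile, denominator: Literal["L", "L-1"] = "L"
) -> FeatureVector:
    """PSSM dipeptide-composition descriptor (400-d).

    Entry (i, j) is ``(1/L) * sum_{k=1}^{L-1} scores[k, i] * scores[k+1, j]``,
    ordered (1,1), (1,2), ..., (20,20).  The ``1/L`` prefactor is the
    printed convention even though the sum has L-1 terms;
    ``denominator="L-1"`` switches to the per-pair mean.
    """
    _require_min_length(profile.length, "PSSM-DPC")
    s = profile.scores
    denom = profile.length if denominator == "L" else profile.length - 1
    dpc = (s[:-1].T @ s[1:]) / denom
    return FeatureVector("PSSM-DPC", dpc.ravel(), profile.protein_id)


def reduce_profile(profile: PssmProfile) -> ReducedProfile:
    """Collapse the 20 PSSM columns to 10 reduced-alphabet columns.

    Per row: G1=(F+Y+W)/3, G2=(M+L)/2, G3=(I+V)/2, G4=(A+T+S)/3,
    G5=(N+H)/2, G6=(Q+E+D)/3, G7=(R+K)/2, G8=C, G9=G, G10=P, where the
    letters denote that row's PSSM columns (so non-standard residues in
    the sequence are routed through their score columns and no row is
    dropped).
    """
    cols = [
        profile.scores[:, [AA_ORDER.index(a) for a in members]].mean(axis=1)
        for _, members in REDUCED_GROUPS
    ]
    return ReducedProfile(np.column_stack(cols), source_id=profile.protein_id)


def encode_rpssm(reduced: ReducedProfile) -> FeatureVector:
    """Reduced-PSSM descriptor (110-d).

    100 pseudo-dipeptide terms
    ``D[s, t] = (1/(2(L-1))) * sum_i (R[i, s] - R[i+1, t])**2`` for
    s, t in 1..10 (row-major), followed by the 10 per-column
    mean-square deviations ``(1/L) * sum_i (R[i, s] - mean_s)**2``.
    """
    _require_min_length(reduced.length, "R-PSSM")
    r = reduced.values
    L = reduced.length
    a, b = r[:-1], r[1:]  # (L-1, 10) consecutive row pairs
    # sum_i (a[i,s] - b[i,t])^2 expanded to avoid an L x 10 x 10 temp
    sq = (
        (a**2).sum(axis=0)[:, None]
        + (b**2).sum(axis=0)[None, :]
        - 2.0 * a.T @ b
    )
    dipeptide = sq / (2.0 * (L - 1))
    dispersion = ((r - r.mean(axis=0)) ** 2).mean(axis=0)
    return FeatureVector(
        "R-PSSM", np.concatenate([dipeptide.ravel(), dispersion]), reduced.source_id
    )


def _encode_rpssm_from_profile(profile: PssmProfile) -> FeatureVector:
    return encode_rpssm(reduce_profile(profile))


#: Registry of descriptor encoders keyed by CLI-friendly name.
DESCRIPTORS: dict[str, Callable[[PssmProfile], FeatureVector]] = {
    "fpssm": encode_fpssm,
    "pssm_dpc": encode_pssm_dpc,
    "rpssm": _encode_rpssm_from_profile,
}
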