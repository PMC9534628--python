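import numpy as np
import pytest

from dbp_idwt.io_profiles import AA_ORDER, PssmProfile


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_profile(scores, sequence=None, protein_id="p"):
    """Build a PssmProfile from a score matrix (sequence defaults to 'A'*L)."""
    scores = np.asarray(scores, dtype=float)
    if sequence is None:
        sequence = "A" * scores.shape[0]
    return PssmProfile(protein_id=protein_id, sequence=sequence, scores=scores)


def random_profile(rng, length, low=-10, high=13, protein_id="p"):
    scores = rng.integers(low, high + 1, size=(length, 20)).astype(float)
    sequence = "".join(rng.choice(list(AA_ORDER), size=length))
    return PssmProfile(protein_id=protein_id, sequence=sequence, scores=scores)


@pytest.fixture
def pssm_file(tmp_path):
    """A hand-written PSI-BLAST ASCII PSSM file: 3 residues ACD, row i
    holding scores i, i+1, ..., i+19 in the standard column order, with
    the percentage block and trailing statistics PSI-BLAST emits."""
    header = "            " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, observed...",
        header,
    ]
    for i, res in enumerate(["A", "C", "D"], start=1):
        scores = " ".join(f"{i + j:>3d}" for j in range(20))
        pcts = " ".join("  5" for _ in range(20))
        lines.append(f"{i:>5} {res} {scores} {pcts}  0.36 0.08")
    lines += ["", "                      K         Lambda", "Standard Ungapped 0.13 0.31"]
    path = tmp_path / "toy.pssm"
    path.write_text("\n".join(lines) + "\n")
    return path
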