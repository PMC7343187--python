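import numpy as np
import pytest

from rimsys.network import BindingReaction, ReactionNetwork, Species


@pytest.fixture
def one_reaction_network():
    """R + L <=> RL at the ATPase-assay concentrations (2.5 / 25 uM, Kd 1)."""
    return ReactionNetwork(
        [Species("R", 2.5), Species("L", 25.0), Species("RL")],
        [BindingReaction("R", "L", "RL", 1.0)],
    )


def square_network(kd_a=1.0, kd_g=1.0, kd_g2=None, kd_a2=None, conc=None, kf=1e9):
    """K/A/G binding square; ternary Kds default to the cycle-closing values."""
    kd_g2 = kd_g if kd_g2 is None else kd_g2
    kd_a2 = kd_a * kd_g2 / kd_g if kd_a2 is None else kd_a2
    conc = conc or {"K": 1.0, "A": 1.0, "G": 1.0}
    return ReactionNetwork(
        [
            Species("K", conc["K"]),
            Species("A", conc["A"]),
            Species("G", conc["G"]),
            Species("KA"),
            Species("KG"),
            Species("KAG"),
        ],
        [
            BindingReaction("K", "A", "KA", kd_a, kf=kf),
            BindingReaction("KA", "G", "KAG", kd_g2, kf=kf),
            BindingReaction("K", "G", "KG", kd_g, kf=kf),
            BindingReaction("KG", "A", "KAG", kd_a2, kf=kf),
        ],
    )


def naive_coverage(reads, reference_length, strand, trim=11):
    """Per-read loop oracle for centre-weighted coverage."""
    counts = np.zeros(reference_length, dtype=np.int64)
    for r in reads:
        if r.strand != strand:
            continue
        for pos in range(r.start + trim, r.start + r.span - trim):
            if 0 <= pos < reference_length:
                counts[pos] += 1
    return counts
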