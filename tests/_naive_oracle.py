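"""Independent, deliberately naive reference implementations.

These are written as plain Python loops with no code shared with the
package, so they can serve as an oracle for the charge-patterning
parameters.  delta_max enumerates distinct charge arrangements through
sympy's multiset permutation generator, a third-party enumeration route
independent of the package's combinatorial code.
"""

from sympy.utilities.iterables import multiset_permutations

_KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
       "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
       "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
       "Y": -1.3, "V": 4.2}

_CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1}


def charges_of(seq):
    return [_CHARGE.get(a, 0) for a in seq]


def naive_fcr_ncpr(seq):
    pos = sum(1 for a in seq if _CHARGE.get(a, 0) > 0)
    neg = sum(1 for a in seq if _CHARGE.get(a, 0) < 0)
    return (pos + neg) / len(seq), (pos - neg) / len(seq)


def naive_mean_hydropathy(seq):
    return sum((_KD[a] + 4.5) / 9.0 for a in seq) / len(seq)


def _sigma(block):
    pos = sum(1 for c in block if c > 0) / len(block)
    neg = sum(1 for c in block if c < 0) / len(block)
    if pos + neg == 0:
        return 0.0
    return (pos - neg) ** 2 / (pos + neg)


def naive_delta(charges, g):
    sigma_seq = _sigma(charges)
    blobs = [charges[i:i + g] for i in range(len(charges) - g + 1)]
    return sum((_sigma(b) - sigma_seq) ** 2 for b in blobs) / len(blobs)


def naive_delta_max(charges, g):
    best = 0.0
    for arrangement in multiset_permutations(list(charges)):
        best = max(best, naive_delta(arrangement, g))
    return best


def crosscheck_panel(n=100, seed=2024, lengths=(8, 10)):
    """Compare package parameters against this oracle on a random panel.

    Returns the maximum absolute differences and the number of panel
    members with a defined kappa; sequences are short enough for the
    oracle's exhaustive delta_max enumeration.
    """
    import numpy as np
    from disorderdb import compute_sequence_parameters

    rng = np.random.default_rng(seed)
    alphabet = list("EEKKDRGSAQ")
    diffs = {"kappa": 0.0, "fcr": 0.0, "ncpr": 0.0, "mean_hydropathy": 0.0}
    n_defined = 0
    mismatched_definedness = 0
    for _ in range(n):
        length = int(rng.integers(lengths[0], lengths[1]))
        seq = "".join(rng.choice(alphabet, length))
        params = compute_sequence_parameters(seq, mode="exhaustive")
        fcr, ncpr = naive_fcr_ncpr(seq)
        diffs["fcr"] = max(diffs["fcr"], abs(params.fcr - fcr))
        diffs["ncpr"] = max(diffs["ncpr"], abs(params.ncpr - ncpr))
        diffs["mean_hydropathy"] = max(
            diffs["mean_hydropathy"],
            abs(params.mean_hydropathy - naive_mean_hydropathy(seq)))
        expected = naive_kappa(seq)
        if (expected is None) != (params.kappa is None):
            mismatched_definedness += 1
        elif expected is not None:
            n_defined += 1
            diffs["kappa"] = max(diffs["kappa"], abs(params.kappa - expected))
    return {"diffs": diffs, "n_kappa_defined": n_defined,
            "mismatched_definedness": mismatched_definedness, "n": n}


def naive_kappa(seq, blob_sizes=(5, 6)):
    """Exhaustive kappa; None when undefined.  Only viable for short sequences."""
    ch = charges_of(seq)
    if all(c == 0 for c in ch) or len(seq) < max(blob_sizes):
        return None
    ratios = []
    for g in blob_sizes:
        d = naive_delta(ch, g)
        dmax = naive_delta_max(ch, g)
        if dmax == 0.0:
            return None
        ratios.append(d / dmax)
    return sum(ratios) / len(ratios)
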