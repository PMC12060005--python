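"""Independent brute-force oracles used to freeze expected values.

Each oracle is deliberately naive (quadratic scans, explicit enumerations,
recursive pathway walks) and shares no code with the implementation paths
it checks.
"""

from itertools import permutations
from math import comb, exp, factorial

# ---------------------------------------------------------------- intervals


def brute_force_intersect(a, b):
    """All overlapping pairs by quadratic scan; (i, j, overlap_bp)."""
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov > 0:
                out.append((i, j, ov))
    out.sort()
    return out


# ------------------------------------------------------------ Poisson tail


def poisson_upper_tail(c, lam):
    """P(X >= c) for X ~ Poisson(lam) by direct series summation."""
    if c <= 0:
        return 1.0
    total = 0.0
    for k in range(0, c):
        total += exp(-lam) * lam**k / factorial(k)
    return 1.0 - total


def binarization_threshold(lam, alpha):
    """Smallest integer c with P(X >= c) < alpha, by linear search."""
    c = 1
    while poisson_upper_tail(c, lam) >= alpha:
        c += 1
    return c


# ---------------------------------------------------------- Fisher's exact


def fisher_exact_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


# ----------------------------------------------------------------- NG86


_BASES = "TCAG"
_CODE = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _CODE[_b1 + _b2 + _b3] = _AA[_i]
            _i += 1
_STOPS = {c for c, aa in _CODE.items() if aa == "*"}


def ng86_sites(codon):
    """(synonymous, nonsynonymous) fractional site counts for one codon.

    Mutations creating a stop codon count as nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in _STOPS and _CODE[mut] == _CODE[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def ng86_substitutions(c1, c2):
    """Pathway-averaged (syn, nonsyn) substitution counts; pathways
    through stop codons are excluded (all kept if every path has one)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, skip_stops):
        cur, syn, nonsyn = c1, 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if skip_stops and nxt in _STOPS and nxt != c2:
                return None
            if _CODE[cur] == _CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    results = [r for r in (walk(o, True) for o in permutations(diff)) if r]
    if not results:
        results = [walk(o, False) for o in permutations(diff)]
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def ng86_kaks(seq1, seq2):
    """Full NG86 Ka/Ks with Jukes-Cantor correction, step by step."""
    from math import log

    S = N = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        ca, cb = seq1[i : i + 3], seq2[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        sa = ng86_sites(ca)
        sb = ng86_sites(cb)
        S += (sa[0] + sb[0]) / 2
        N += (sa[1] + sb[1]) / 2
        s, n = ng86_substitutions(ca, cb)
        sd += s
        nd += n
    ps, pn = sd / S, nd / N

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * log(1 - 4 * p / 3)

    return {"S": S, "N": N, "sd": sd, "nd": nd, "ka": jc(pn), "ks": jc(ps)}


def random_codon_pair(rng, n_codons, p_sub=0.1):
    """A random gap-free codon alignment without stop codons."""
    codons = [c for c in _CODE if c not in _STOPS]
    while True:
        a = [codons[rng.integers(0, len(codons))] for _ in range(n_codons)]
        b = []
        for cod in a:
            cod2 = list(cod)
            for pos in range(3):
                if rng.random() < p_sub:
                    cod2[pos] = _BASES[rng.integers(0, 4)]
            b.append("".join(cod2))
        if any("".join(x) in _STOPS for x in b):
            continue
        return "".join(a), "".join(b)
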