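"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

Synonymous and nonsynonymous site counts are averaged over the two
sequences; multi-nucleotide codon differences average the substitution
classification over all minimal mutational pathways, excluding pathways
that pass through a stop codon.  Proportions are corrected for multiple
hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), applied
separately to the synonymous and nonsynonymous proportions.

Changes that create a stop codon count as nonsynonymous in the site
tally; codon columns containing a gap in either sequence are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

_BASES = "TCAG"
_CODONS = ["".join(p) for p in product(_BASES, repeat=3)]

# Standard genetic code (NCBI table 1).
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE = dict(zip(_CODONS, _AA))
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


class AlignmentError(ValueError):
    pass


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float  # NaN when Ks == 0 or a correction is undefined
    syn_sites: float
    nonsyn_sites: float
    syn_subs: float
    nonsyn_subs: float
    saturated: bool = False  # a JC correction hit p >= 3/4


def _syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts for one codon."""
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa and mutant not in STOP_CODONS:
                syn += 1 / 3
    return syn, 3.0 - syn


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) substitution counts
    between two codons; paths through stop codons are excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = c1
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        # every ordering crosses a stop: fall back to counting all paths
        for order in permutations(diff):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    syn_tot += 1
                else:
                    nonsyn_tot += 1
                cur = nxt
            n_paths += 1
    return syn_tot / n_paths, nonsyn_tot / n_paths


_SITE_CACHE = {c: _syn_nonsyn_sites(c) for c in _CODONS if c not in STOP_CODONS}


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; undefined (NaN) at p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1 - 4 * p / 3)


def _clean_codons(a: str, b: str) -> list[tuple[str, str]]:
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise AlignmentError("aligned sequences differ in length")
    if len(a) % 3:
        raise AlignmentError("alignment length not divisible by 3")
    ok = set("ACGT-")
    if set(a) - ok or set(b) - ok:
        raise AlignmentError("sequences may contain only A/C/G/T/-")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        pairs.append((ca, cb))
    n_cod = len(pairs)
    for j, (ca, cb) in enumerate(pairs):
        internal = j < n_cod - 1
        for c in (ca, cb):
            if c in STOP_CODONS and internal:
                raise AlignmentError(f"internal stop codon {c}")
    # a terminal stop present in both carries no rate information; drop it
    if pairs and (pairs[-1][0] in STOP_CODONS or pairs[-1][1] in STOP_CODONS):
        pairs = pairs[:-1]
    return pairs


def kaks_ng86(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka, Ks and their ratio for one gap-aligned CDS pair.

    Symmetric in its arguments; per-site rates, so self-concatenation
    leaves the result unchanged.  The ratio is NaN when Ks = 0.
    """
    pairs = _clean_codons(seq1, seq2)
    if not pairs:
        raise AlignmentError("no ungapped codon columns")
    S = N = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        sa, na = _SITE_CACHE[ca]
        sb, nb = _SITE_CACHE[cb]
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = _path_counts(ca, cb)
        sd += s
        nd += n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = bool(np.isnan(ks) or np.isnan(ka))
    if saturated or ks == 0 or np.isnan(ks):
        ratio = float("nan")
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=float(ka),
        ks=float(ks),
        ratio=ratio,
        syn_sites=S,
        nonsyn_sites=N,
        syn_subs=sd,
        nonsyn_subs=nd,
        saturated=saturated,
    )
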