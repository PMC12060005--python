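"""Gene-level chromatin signatures.

Chromatin states are grouped into four functional categories (active,
polycomb, heterochromatin, mixed) plus a background null; the set of
categories overlapping a gene body defines one of 16 signatures.  Each
signature carries a broad class (active / repressive / mixed) from its
composition, and an expression-based binary class from a rank test of its
genes' abundance against the rest of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, spearmanr, wilcoxon
from statsmodels.stats.multitest import multipletests

from .core import GeneAnnotation, GenomeModel
from .hmm import HMMModel, Segmentation

#: The seven profiled histone marks and their transcriptional role.
MARK_ROLES: dict[str, str] = {
    "H3K27ac": "active",
    "H3K4me3": "active",
    "H4K16ac": "active",
    "H3K36me3": "active",
    "H3K27me3": "polycomb",
    "H3K9me2": "heterochromatin",
    "H3K9me3": "heterochromatin",
}

CATEGORIES = ("active", "polycomb", "heterochromatin", "mixed")


def categorize_states(
    model: HMMModel,
    roles: Mapping[str, str] | None = None,
    tau: float = 0.5,
) -> dict[int, str]:
    """Map each HMM state (1-based id) to a functional category.

    A mark is *enriched* in a state iff its emission probability reaches
    ``tau``.  Only-active -> active; only-H3K27me3 -> polycomb; only
    H3K9me2/3 (optionally with H3K27me3) -> heterochromatin; at least one
    active plus at least one repressive mark -> mixed; nothing enriched ->
    null.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    roles = dict(roles or MARK_ROLES)
    out: dict[int, str] = {}
    for k in range(model.n_states):
        enriched = {
            roles[m]
            for m, p in zip(model.mark_names, model.emissionprob[k])
            if p >= tau
        }
        has_active = "active" in enriched
        has_rep = bool(enriched & {"polycomb", "heterochromatin"})
        if not enriched:
            cat = "null"
        elif has_active and has_rep:
            cat = "mixed"
        elif has_active:
            cat = "active"
        elif "heterochromatin" in enriched:
            cat = "heterochromatin"
        else:
            cat = "polycomb"
        out[k + 1] = cat
    return out


@dataclass(frozen=True)
class SignatureDef:
    signature: str  # S1..S16
    categories: frozenset  # subset of CATEGORIES; empty = null-only
    broad_class: str  # active / repressive / mixed


def _broad_class(cats: frozenset) -> str:
    if not cats:
        return "repressive"  # null-only
    if "active" in cats and cats <= {"active", "mixed"}:
        return "active"
    if cats <= {"polycomb", "heterochromatin", "mixed"} and cats & {
        "polycomb",
        "heterochromatin",
    }:
        return "repressive"
    return "mixed"


def enumerate_signatures() -> list[SignatureDef]:
    """The 16 signatures: all non-empty category subsets plus null-only.

    Numbering is canonical by class: S1 null-only, S2-S7 the remaining
    repressive-class subsets, S8-S14 the mixed-class subsets, S15-S16 the
    active-class subsets ({active, mixed} then {active}).
    """
    subsets = [frozenset()]
    for i in range(1, 16):
        subsets.append(
            frozenset(c for bit, c in enumerate(CATEGORIES) if i >> bit & 1)
        )

    def order_key(cats: frozenset):
        cls = _broad_class(cats)
        cls_rank = {"repressive": 0, "mixed": 1, "active": 2}[cls]
        null_first = 0 if not cats else 1
        # within-class: by size then by category order, {active,mixed} before {active}
        if cls == "active":
            inner = (-len(cats),)
        else:
            inner = (
                len(cats),
                tuple(sorted(CATEGORIES.index(c) for c in cats)),
            )
        return (cls_rank, null_first, inner)

    ordered = sorted(subsets, key=order_key)
    return [
        SignatureDef(signature=f"S{i + 1}", categories=cats, broad_class=_broad_class(cats))
        for i, cats in enumerate(ordered)
    ]


_SIGNATURE_BY_SET = {d.categories: d for d in enumerate_signatures()}


def signature_of(categories: set[str] | frozenset) -> SignatureDef:
    """Signature for the category set found on a gene ('null' drops out)."""
    key = frozenset(c for c in categories if c != "null")
    return _SIGNATURE_BY_SET[key]


def gene_signatures(
    seg: Segmentation,
    catmap: Mapping[int, str],
    genes: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Per-gene chromatin signature from the states on the gene body.

    The category set collects every state overlapping the body by >= 1 bp.
    Returns a frame indexed by gene_id with ``categories``, ``signature``
    and ``broad_class`` columns.
    """
    rows = []
    bs = seg.bin_size
    for g in genes:
        path = seg.bin_states.get(g.body.chrom)
        if path is None:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.body.chrom}")
        first = g.body.start // bs
        last = min((g.body.end - 1) // bs, len(path) - 1)
        cats = {catmap[int(s) + 1] for s in np.unique(path[first : last + 1])}
        sig = signature_of(cats)
        rows.append(
            {
                "gene_id": g.gene_id,
                "categories": ",".join(sorted(cats)),
                "signature": sig.signature,
                "broad_class": sig.broad_class,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def signature_expression_tests(
    sig_table: pd.DataFrame,
    expression: pd.Series,
    alpha: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-signature rank test of member-gene expression vs the rest.

    ``expression`` is one value per gene (replicate-mean TPM for the
    matching sex and tissue); the caller restricts both inputs to the gene
    universe of interest (autosomal + pseudoautosomal).  The main test is
    the two-sample rank-sum (one-sided, greater); a one-sample signed-rank
    test against the genomic median is reported alongside.  A signature is
    expression-class *active* iff its one-sided rank-sum p < alpha;
    signatures with fewer than ``min_genes`` genes are skipped and default
    to repressive (flagged in ``tested``).
    """
    genes = sig_table.index.intersection(expression.index)
    sig = sig_table.loc[genes, "signature"]
    expr = expression.loc[genes].astype(float)
    global_median = float(expr.median())
    rows = []
    for d in enumerate_signatures():
        members = expr[sig == d.signature]
        rest = expr[sig != d.signature]
        if len(members) < min_genes or len(rest) < min_genes:
            rows.append(
                {
                    "signature": d.signature,
                    "n": len(members),
                    "tested": False,
                    "p_greater": np.nan,
                    "p_signed_rank": np.nan,
                    "expression_class": "repressive",
                }
            )
            continue
        stat, p = mannwhitneyu(members, rest, alternative="greater")
        diffs = members - global_median
        if np.all(diffs == 0):
            p_sr = 1.0
        else:
            p_sr = float(
                wilcoxon(diffs[diffs != 0], alternative="greater").pvalue
            )
        rows.append(
            {
                "signature": d.signature,
                "n": len(members),
                "tested": True,
                "statistic": float(stat),
                "p_greater": float(p),
                "p_signed_rank": p_sr,
                "expression_class": "active" if p < alpha else "repressive",
            }
        )
    out = pd.DataFrame(rows).set_index("signature")
    tested = out["tested"] & out["p_greater"].notna()
    padj = np.full(len(out), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = multipletests(
            out.loc[tested, "p_greater"], method="fdr_bh"
        )[1]
    out["p_bh"] = padj
    return out


def expression_class_by_gene(
    sig_table: pd.DataFrame, tests: pd.DataFrame
) -> pd.Series:
    """Expression-based binary chromatin class per gene (active/repressive)."""
    mapping = tests["expression_class"]
    return sig_table["signature"].map(mapping).rename("expression_class")


def fisher_r_to_z(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """z statistic and two-sided p for the difference of two independent
    correlation coefficients (variance-stabilising atanh transform)."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    cap = 1 - 1e-15  # atanh is infinite at |r| = 1
    r1 = float(np.clip(r1, -cap, cap))
    r2 = float(np.clip(r2, -cap, cap))
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)


def te_h3k9_correlation(
    expression: pd.Series,
    mark_cpkm: pd.Series,
    genes: Sequence[GeneAnnotation],
) -> dict:
    """Spearman expression~enrichment correlation for TE-in-intron genes vs
    genes without TEs, compared by Fisher r-to-z.

    Genes with TEs overlapping exons are excluded entirely.
    """
    te_ids = [g.gene_id for g in genes if g.te_in_intron and not g.te_in_exon]
    no_ids = [
        g.gene_id for g in genes if not g.te_in_intron and not g.te_in_exon
    ]
    common = expression.index.intersection(mark_cpkm.index)
    te_ids = [g for g in te_ids if g in common]
    no_ids = [g for g in no_ids if g in common]
    if len(te_ids) <= 3 or len(no_ids) <= 3:
        raise ValueError("need more than 3 genes in each TE group")
    rho_te, p_te = spearmanr(expression[te_ids], mark_cpkm[te_ids])
    rho_no, p_no = spearmanr(expression[no_ids], mark_cpkm[no_ids])
    z, p = fisher_r_to_z(rho_te, len(te_ids), rho_no, len(no_ids))
    return {
        "rho_te": float(rho_te),
        "p_te": float(p_te),
        "n_te": len(te_ids),
        "rho_no_te": float(rho_no),
        "p_no_te": float(p_no),
        "n_no_te": len(no_ids),
        "z": z,
        "p_diff": p,
    }
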