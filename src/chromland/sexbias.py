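"""Sex-biased expression calls and chromatin-concordance tests.

The differential-expression rule is a moderated two-sample t on
log2(TPM + 0.5) with per-gene variances shrunk toward the genome-wide
replicate variance; a gene is biased when the BH-adjusted p is below the
FDR threshold and the fold change exceeds the threshold.  The
"open in same sex / closed in opposite" model is tested on the four-way
concordance of the two sexes' expression-based chromatin classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5
DISCORDANT_CLASSES = (
    "male-active/female-repressive",
    "female-active/male-repressive",
)


@dataclass
class SexBiasConfig:
    fold_change: float = 2.0
    fdr: float = 0.05
    tpm_floor: float = 0.1
    prior_df: float = 4.0

    def __post_init__(self) -> None:
        if min(self.fold_change, self.fdr, self.tpm_floor) <= 0:
            raise ValueError("thresholds must be positive")


def _sex_columns(tpm: pd.DataFrame, sex: str, tissue: str) -> pd.DataFrame:
    """Columns for one sex/tissue from a (sex, tissue, replicate)
    MultiIndex frame, or from flat ``sex_tissue_repN`` labels."""
    if isinstance(tpm.columns, pd.MultiIndex):
        return tpm.loc[:, (sex, tissue)]
    cols = [c for c in tpm.columns if c.startswith(f"{sex}_{tissue}_")]
    return tpm[cols]


def call_sex_bias(
    tpm: pd.DataFrame,
    tissue: str,
    config: SexBiasConfig | None = None,
) -> pd.DataFrame:
    """Per-gene sex-bias call in one tissue.

    Genes whose replicate-mean TPM stays at or below the floor in both
    sexes are ``filtered`` and excluded from testing; fold change is
    female over male on log2(TPM + 0.5).  Doubling every TPM leaves calls
    unchanged (the rule is ratio-based).
    """
    config = config or SexBiasConfig()
    female = _sex_columns(tpm, "female", tissue)
    male = _sex_columns(tpm, "male", tissue)
    nf, nm = female.shape[1], male.shape[1]
    if nf < 2 or nm < 2:
        raise ValueError("need >= 2 replicates per sex")

    lf = np.log2(female + PSEUDOCOUNT)
    lm = np.log2(male + PSEUDOCOUNT)
    mean_f, mean_m = lf.mean(axis=1), lm.mean(axis=1)
    log2fc = mean_f - mean_m
    s2 = (lf.var(axis=1, ddof=1) * (nf - 1) + lm.var(axis=1, ddof=1) * (nm - 1)) / (
        nf + nm - 2
    )

    filtered = (female.mean(axis=1) <= config.tpm_floor) & (
        male.mean(axis=1) <= config.tpm_floor
    )
    tested = ~filtered
    d0 = config.prior_df
    d_g = nf + nm - 2
    s2_prior = float(s2[tested].mean()) if tested.any() else 0.0
    s2_mod = (d0 * s2_prior + d_g * s2) / (d0 + d_g)
    se = np.sqrt(s2_mod * (1 / nf + 1 / nm))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / se
    df = d0 + d_g
    p = 2 * t_dist.sf(np.abs(tstat), df)
    p = pd.Series(p, index=tpm.index)

    padj = pd.Series(np.nan, index=tpm.index)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    lfc_thresh = np.log2(config.fold_change)
    klass = pd.Series("unbiased", index=tpm.index)
    klass[filtered] = "filtered"
    biased = tested & (padj < config.fdr) & (log2fc.abs() > lfc_thresh)
    klass[biased & (log2fc > 0)] = "female-biased"
    klass[biased & (log2fc < 0)] = "male-biased"

    return pd.DataFrame(
        {
            "tissue": tissue,
            "class": klass,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
        }
    )


def concordance(
    class_female: pd.Series, class_male: pd.Series
) -> pd.Series:
    """Four-way chromatin concordance from the two sexes' binary classes.

    Genes missing a class in either sex are dropped; the count of skipped
    genes is recorded in ``.attrs['n_skipped']``.
    """
    common = class_female.dropna().index.intersection(class_male.dropna().index)
    skipped = len(class_female.index.union(class_male.index)) - len(common)
    f = class_female.loc[common]
    m = class_male.loc[common]
    out = pd.Series("both-active", index=common, name="concordance")
    out[(f == "repressive") & (m == "repressive")] = "both-repressive"
    out[(f == "repressive") & (m == "active")] = "male-active/female-repressive"
    out[(f == "active") & (m == "repressive")] = "female-active/male-repressive"
    out.attrs["n_skipped"] = skipped
    return out


def test_open_closed_model(
    calls: pd.DataFrame, conc: pd.Series
) -> dict:
    """Chi-square + per-direction Fisher tests of the open/closed model.

    (a) chi-square on the bias-class x concordance-class table;
    (b) for each sex, Fisher's exact 2x2 of that sex's biased genes versus
    the rest against the matching discordant chromatin class versus the
    rest.  Positive enrichment (odds ratio > 1) in both directions is the
    model's prediction.
    """
    common = calls.index.intersection(conc.index)
    bias = calls.loc[common, "class"]
    keep = bias != "filtered"
    bias, cc = bias[keep], conc.loc[common][keep]
    if bias.nunique() < 2:
        raise ValueError("need at least two bias classes present")
    table = pd.crosstab(bias, cc)
    chi2, p_chi2, dof, expected = chi2_contingency(table)
    if (expected < 1).all():
        raise ValueError("all expected cell counts < 1; test refused")

    def direction(sex: str) -> dict:
        biased = bias == f"{sex}-biased"
        matching = cc == (
            "male-active/female-repressive"
            if sex == "male"
            else "female-active/male-repressive"
        )
        t2 = np.array(
            [
                [(biased & matching).sum(), (biased & ~matching).sum()],
                [(~biased & matching).sum(), (~biased & ~matching).sum()],
            ]
        )
        odds, p = fisher_exact(t2, alternative="two-sided")
        return {
            "table": t2,
            "odds_ratio": float(odds),
            "p": float(p),
            "enriched": bool(odds > 1),
        }

    return {
        "table": table,
        "chi2": float(chi2),
        "p_chi2": float(p_chi2),
        "dof": int(dof),
        "male": direction("male"),
        "female": direction("female"),
    }


def signature_composition_by_bias(
    calls: pd.DataFrame,
    sig_female: pd.DataFrame,
    sig_male: pd.DataFrame,
) -> dict:
    """Broad-class composition of each bias class in each sex's chromatin,
    with a cross-sex Fisher comparison of the repressive share.

    ``sig_female``/``sig_male`` are gene-signature tables for the same
    tissue in the two sexes.  Per bias class the broad-class proportions
    sum to 1; empty bias classes are flagged.
    """
    out_rows = []
    fisher = {}
    for bias_class in ("male-biased", "female-biased", "unbiased"):
        genes = calls.index[calls["class"] == bias_class]
        counts = {}
        for sex, sig in (("female", sig_female), ("male", sig_male)):
            sub = sig.loc[sig.index.intersection(genes), "broad_class"]
            n = len(sub)
            for cls in ("active", "mixed", "repressive"):
                out_rows.append(
                    {
                        "bias_class": bias_class,
                        "chromatin_sex": sex,
                        "broad_class": cls,
                        "n": int((sub == cls).sum()),
                        "proportion": float((sub == cls).mean()) if n else np.nan,
                        "empty": n == 0,
                    }
                )
            counts[sex] = (int((sub == "repressive").sum()), n)
        (rf, nf), (rm, nm) = counts["female"], counts["male"]
        if nf and nm:
            odds, p = fisher_exact([[rf, nf - rf], [rm, nm - rm]])
            fisher[bias_class] = {"odds_ratio": float(odds), "p": float(p)}
        else:
            fisher[bias_class] = {"odds_ratio": np.nan, "p": np.nan}
    return {"proportions": pd.DataFrame(out_rows), "fisher_cross_sex": fisher}
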