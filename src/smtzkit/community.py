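"""Downstream amplicon analytics on an ASV count table.

Operates on the output of a standard denoising pipeline: relative
abundances, aggregation to a taxonomic rank, functional-guild fractions
(methane-cycling archaea, sulfate reducers), alpha diversity (Shannon,
Simpson, Chao1), and Bray-Curtis dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from smtzkit.io import ASVTable, GuildDefinition, TaxonomyTable, ValidationError


@dataclass
class GuildProfile:
    """Per-sample guild fractions and pooled within-guild composition.

    ``fractions``: samples x guilds, guild reads / total sample reads.
    ``composition``: per guild, the share of each member taxon among all
    reads the guild drew across samples (empty for guilds with no reads).
    ``membership``: guild -> list of member ASV ids.
    """

    fractions: pd.DataFrame
    composition: dict[str, pd.Series]
    membership: dict[str, list[str]]


@dataclass
class DiversityResult:
    """Per-sample alpha diversity: Shannon (natural log by default),
    Simpson (1 - sum p^2), bias-corrected Chao1, and observed richness."""

    shannon: pd.Series
    simpson: pd.Series
    chao1: pd.Series
    observed: pd.Series


def relative_abundance(t: ASVTable) -> pd.DataFrame:
    """Per-sample ASV fractions; each row sums to 1.

    Raises on samples with zero total reads (a fraction is undefined there).
    """
    totals = t.counts.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise ValidationError(
            f"samples with zero total reads: {list(empty.index)}"
        )
    return t.counts.div(totals, axis=0)


def aggregate_taxa(
    t: ASVTable, tax: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Sum counts to a taxonomic rank (samples x taxa).

    ASVs with no assignment at that rank are grouped under ``"unassigned"``;
    sample totals are conserved exactly.
    """
    labels = tax.rank(rank).reindex(t.asv_ids).fillna("unassigned")
    return t.counts.T.groupby(labels.to_numpy()).sum().T


def _match_guilds(
    tax: TaxonomyTable, g: GuildDefinition, asv_ids: list[str]
) -> dict[str, list[str]]:
    """ASV membership per guild; overlapping definitions are a config error."""
    data = tax.data.reindex(asv_ids)
    membership: dict[str, list[str]] = {}
    claimed: dict[str, str] = {}
    conflicts = []
    for guild, matchers in g.guilds.items():
        mask = np.zeros(len(asv_ids), bool)
        for rank, taxon in matchers:
            mask |= (data[rank] == taxon).to_numpy()
        members = [a for a, m in zip(asv_ids, mask) if m]
        for a in members:
            if a in claimed and claimed[a] != guild:
                conflicts.append((a, claimed[a], guild))
            claimed[a] = guild
        membership[guild] = members
    if conflicts:
        raise ValidationError(
            "overlapping guild definitions: "
            + "; ".join(f"{a} matched by {g1!r} and {g2!r}" for a, g1, g2 in conflicts)
        )
    return membership


def guild_fraction(
    t: ASVTable, tax: TaxonomyTable, g: GuildDefinition, rank: str = "genus"
) -> GuildProfile:
    """Fraction of each sample's reads belonging to each guild, plus the
    pooled within-guild composition.

    The within-guild composition labels member ASVs by ``rank`` (falling back
    to the ASV id when unassigned) and reports each label's share of the
    guild's pooled reads, summing to 1 for guilds with any reads.
    """
    membership = _match_guilds(tax, g, t.asv_ids)
    totals = t.counts.sum(axis=1)
    fractions = pd.DataFrame(index=t.counts.index)
    composition: dict[str, pd.Series] = {}
    for guild, members in membership.items():
        guild_counts = t.counts[members] if members else None
        if guild_counts is None or guild_counts.size == 0:
            fractions[guild] = 0.0
            composition[guild] = pd.Series(dtype=float)
            continue
        fractions[guild] = guild_counts.sum(axis=1) / totals
        pooled = guild_counts.sum(axis=0)
        total = pooled.sum()
        if total > 0:
            labels = tax.rank(rank).reindex(members)
            labels = labels.fillna(pd.Series(members, index=members))
            composition[guild] = pooled.groupby(labels.to_numpy()).sum() / total
        else:
            composition[guild] = pd.Series(dtype=float)
    return GuildProfile(fractions=fractions, composition=composition, membership=membership)


def shannon_index(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy -sum(p ln p) over nonzero fractions (natural log
    unless ``base`` is given)."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    h = float(-np.sum(p * np.log(p)))
    return h / np.log(base) if base else h


def simpson_index(counts: np.ndarray) -> float:
    """Gini-Simpson diversity 1 - sum p^2."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts / total
    return float(1.0 - np.sum(p**2))


def chao1_index(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default (finite even
    with no doubletons); classical form S_obs + F1^2/(2 F2) available.
    """
    counts = np.asarray(counts)
    s_obs = int(np.sum(counts > 0))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float("inf") if f1 > 0 else float(s_obs)
    return s_obs + f1**2 / (2.0 * f2)


def alpha_diversity(
    t: ASVTable, base: float | None = None, pooled: bool = False
) -> DiversityResult:
    """Alpha diversity per sample, or of the pooled count table.

    With ``pooled=True`` all samples are summed before computing the indices
    (the convention behind whole-study single numbers); the result then has a
    single row labelled ``"pooled"``.
    """
    counts = t.counts
    if pooled:
        counts = counts.sum(axis=0).to_frame("pooled").T
    sh, si, ch, ob = {}, {}, {}, {}
    for sample, row in counts.iterrows():
        arr = row.to_numpy()
        sh[sample] = shannon_index(arr, base)
        si[sample] = simpson_index(arr)
        ch[sample] = chao1_index(arr)
        ob[sample] = int(np.sum(arr > 0))
    return DiversityResult(
        shannon=pd.Series(sh, name="shannon"),
        simpson=pd.Series(si, name="simpson"),
        chao1=pd.Series(ch, name="chao1"),
        observed=pd.Series(ob, name="observed"),
    )


def bray_curtis(t: ASVTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity matrix.

    BC(i, j) = 1 - 2 sum(min(x_i, x_j)) / (sum x_i + sum x_j); symmetric with
    zero diagonal, values in [0, 1].
    """
    if len(t.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    mat = squareform(pdist(t.counts.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(mat, index=t.sample_ids, columns=t.sample_ids)
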