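"""iBAQ label-free quantification and downstream statistics.

iBAQ (intensity-based absolute quantification) divides each protein's
search-engine intensity by its number of theoretical fully tryptic
peptides — fragments obtained by cleaving after every K or R (by default
not before P, the Keil rule), with zero missed cleavages, keeping lengths
6..30 inclusive.  Per-sample iBAQ values are then normalised to the total
over all quantified proteins, so each sample's normalised column sums to
one; this absorbs run-to-run loading differences.

Differential analysis runs Welch's two-sample t-test on normalised iBAQ
per protein, with Benjamini-Hochberg FDR within the contrast.  Fold
changes are log2 ratios of group means after half-minimum imputation of
zeros (imputation affects the fold change only, never the test).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    GroupDesign,
    IBAQTable,
    PathwayGeneSet,
    ProteinSeq,
    UsageError,
    ValidationError,
    validate_intensity_matrix,
)

logger = logging.getLogger("herbnet")

CLEAVE_AFTER = frozenset("KR")


def tryptic_fragments(sequence: str, proline_rule: bool = True) -> list[str]:
    """All zero-missed-cleavage tryptic fragments of a sequence, in order.

    Cleaves after every K or R; with ``proline_rule`` the bond is left
    intact when the next residue is P.  Ambiguity codes (X, B, Z, U) count
    toward fragment length and are never cleavage sites.  Concatenating
    the returned fragments reconstructs the input.
    """
    frags: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in CLEAVE_AFTER and i + 1 < len(sequence):
            if proline_rule and sequence[i + 1] == "P":
                continue
            frags.append(sequence[start : i + 1])
            start = i + 1
    frags.append(sequence[start:])
    return [f for f in frags if f]


def count_theoretical_peptides(
    seq: ProteinSeq | str,
    min_len: int = 6,
    max_len: int = 30,
    proline_rule: bool = True,
) -> int:
    """Count fully tryptic peptides with min_len <= length <= max_len."""
    if min_len > max_len:
        raise UsageError(f"min_len {min_len} > max_len {max_len}")
    sequence = seq.sequence if isinstance(seq, ProteinSeq) else seq
    if not sequence:
        raise UsageError("empty sequence")
    return sum(
        min_len <= len(f) <= max_len
        for f in tryptic_fragments(sequence.upper(), proline_rule=proline_rule)
    )


def compute_ibaq(intensities: pd.DataFrame, counts: Mapping[str, int]) -> IBAQTable:
    """Raw and total-normalised iBAQ from intensities and peptide counts.

    Every accession in the matrix must have a count entry.  Proteins with
    a zero count have an undefined iBAQ and are excluded (logged); each
    sample's normalised column divides by its raw-iBAQ total, which must
    be positive.
    """
    intensities = validate_intensity_matrix(intensities)
    missing = [a for a in intensities.index if a not in counts]
    if missing:
        raise UsageError(f"no theoretical peptide count for: {missing}")
    zero = [a for a in intensities.index if counts[a] == 0]
    if zero:
        logger.warning("compute_ibaq: %d protein(s) with zero countable peptides excluded: %s",
                       len(zero), zero[:10])
    keep = [a for a in intensities.index if counts[a] > 0]
    mat = intensities.loc[keep]
    divisor = pd.Series({a: float(counts[a]) for a in keep})
    raw = mat.div(divisor, axis=0)
    totals = raw.sum(axis=0)
    dead = totals.index[totals == 0].tolist()
    if dead:
        raise ValidationError(f"sample(s) with zero total iBAQ: {dead}")
    norm = raw.div(totals, axis=1)
    return IBAQTable(raw=raw, norm=norm, excluded=tuple(zero))


_P_FLOOR = float(np.finfo(float).tiny)  # zero-variance, unequal means


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else _P_FLOOR
    with warnings.catch_warnings():
        # near-identical values trigger a scipy precision note; the
        # fully-degenerate case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def differential(
    ibaq: IBAQTable,
    design: GroupDesign,
    contrast: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein differential test between two groups on normalised iBAQ.

    ``contrast = (A, B)`` yields ``log2fc = log2(mean_B / mean_A)`` — a
    positive value means higher in B.  Zeros are replaced, for the fold
    change only, by half the smallest nonzero normalised iBAQ in the whole
    matrix; Welch's t-test runs on the unimputed values.  A protein with
    zero variance and equal means in both groups gets p = 1 (no evidence
    of change).

    Returns columns accession, log2fc, p, fdr, flag_p05, flag_fdr05,
    sorted by accession.
    """
    group_a, group_b = contrast
    design.require_groups([group_a, group_b], min_n=2)
    cols_a = design.samples(group_a)
    cols_b = design.samples(group_b)
    missing = [s for s in cols_a + cols_b if s not in ibaq.norm.columns]
    if missing:
        raise UsageError(f"design samples absent from iBAQ table: {missing}")
    norm = ibaq.norm
    nz = norm.to_numpy()
    nz = nz[nz > 0]
    half_min = 0.5 * float(nz.min()) if nz.size else 1.0
    imputed = norm.where(norm > 0, half_min)

    a = norm[cols_a].to_numpy(dtype=float)
    b = norm[cols_b].to_numpy(dtype=float)
    mean_a = imputed[cols_a].mean(axis=1).to_numpy()
    mean_b = imputed[cols_b].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_b / mean_a)
    pvals = np.array([_welch_p(a[i], b[i]) for i in range(norm.shape[0])])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "accession": norm.index,
        "log2fc": log2fc,
        "p": pvals,
        "fdr": fdr,
        "flag_p05": pvals < alpha,
        "flag_fdr05": fdr < alpha,
    })
    return out.sort_values("accession", kind="mergesort").reset_index(drop=True)


def anova_across_groups(ibaq: IBAQTable, design: GroupDesign,
                        groups: Sequence[str] | None = None) -> pd.DataFrame:
    """One-way ANOVA across all (or the named) groups per protein.

    Offered as an alternative omnibus test to pairwise Welch contrasts.
    """
    labels = list(groups) if groups else design.group_labels()
    design.require_groups(labels, min_n=2)
    arrays = [ibaq.norm[design.samples(g)].to_numpy(dtype=float) for g in labels]
    pvals = []
    for i in range(ibaq.norm.shape[0]):
        samples = [arr[i] for arr in arrays]
        if all(s.var(ddof=1) == 0.0 for s in samples):
            means = {s.mean() for s in samples}
            pvals.append(1.0 if len(means) == 1 else _P_FLOOR)
        else:
            pvals.append(float(stats.f_oneway(*samples).pvalue))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"accession": ibaq.norm.index, "p": pvals, "fdr": fdr}) \
        .sort_values("accession", kind="mergesort").reset_index(drop=True)


def enrich(
    selected: Iterable[str],
    background: Iterable[str],
    gene_sets: Sequence[PathwayGeneSet],
    mapping: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets.

    ``selected`` and ``background`` are protein accessions (or gene ids if
    no mapping is given).  A mapping frame (columns target_id, accession)
    translates accessions to the gene-set namespace: a gene counts as
    selected/background if any of its mapped accessions is.

    Per set: k = hits in selected, K = set ∩ background, N = |background|,
    n = |selected|; p = P[Hypergeom(N, K, n) >= k]; BH FDR across sets.
    """
    selected = set(selected)
    background = set(background)
    if not background:
        raise UsageError("empty background")
    if not selected <= background:
        raise UsageError("selected set is not a subset of the background")
    if mapping is not None:
        by_gene = mapping.groupby("target_id")["accession"].agg(set)
        genes_bg = {g for g, accs in by_gene.items() if accs & background}
        genes_sel = {g for g, accs in by_gene.items() if accs & selected}
        background, selected = genes_bg, genes_sel
        if not background:
            raise UsageError("no background accession maps to a gene")
    N, n = len(background), len(selected)
    rows = []
    for s in gene_sets:
        in_bg = s.members & background
        K = len(in_bg)
        k = len(in_bg & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({
            "pathway_id": s.pathway_id, "name": s.name,
            "k": k, "K": K, "N": N, "n": n, "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)
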