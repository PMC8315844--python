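"""Relative quantification by 2^-ddCt and qPCR/sequencing concordance.

The Livak method: per sample, the target gene's Ct is normalized against a
same-sample reference gene (dCt = Ct_gene - Ct_ref, averaging technical
replicates first); ddCt is the difference of condition means of dCt
(treated minus control); the fold change is 2^-ddCt, assuming amplification
efficiency exactly 2. Concordance with sequencing is sign agreement between
log2 of the qPCR fold change and the sequencing log2FC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "condition", "gene_id", "reference_id", "ct")


def _validate_ct(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    bad = set(table["condition"]) - {"control", "treated"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")


def ddct_fold_change(table: pd.DataFrame, gene_id: str) -> float:
    """Fold change (treated vs control) of one gene by 2^-ddCt.

    Technical replicates are averaged per (sample, gene) before
    normalization; every sample measuring the gene must also measure its
    reference gene.
    """
    _validate_ct(table)
    gene_rows = table[table["gene_id"] == gene_id]
    if gene_rows.empty:
        raise ValueError(f"gene {gene_id!r} not in Ct table")
    refs = set(gene_rows["reference_id"])
    if len(refs) != 1:
        raise ValueError(f"gene {gene_id!r} has multiple references: {sorted(refs)}")
    ref_id = refs.pop()

    mean_ct = (table.groupby(["sample_id", "condition", "gene_id"])["ct"]
               .mean().reset_index())
    gene_ct = mean_ct[mean_ct["gene_id"] == gene_id].set_index("sample_id")
    ref_ct = mean_ct[mean_ct["gene_id"] == ref_id].set_index("sample_id")

    dct = {}
    for sample, row in gene_ct.iterrows():
        if sample not in ref_ct.index:
            raise ValueError(
                f"sample {sample!r} measures {gene_id!r} but not its reference "
                f"{ref_id!r}")
        dct[sample] = (row["ct"] - ref_ct.loc[sample, "ct"], row["condition"])

    by_cond: dict[str, list[float]] = {"control": [], "treated": []}
    for value, cond in dct.values():
        by_cond[cond].append(value)
    for cond, vals in by_cond.items():
        if not vals:
            raise ValueError(f"gene {gene_id!r} has no {cond} measurements")
    ddct = float(np.mean(by_cond["treated"]) - np.mean(by_cond["control"]))
    return float(2.0 ** (-ddct))


def concordance(qpcr_fc: dict[str, float], seq_lfc: dict[str, float]) -> dict:
    """Per-gene sign agreement between qPCR fold changes and sequencing log2FC.

    A gene agrees iff sign(log2(qpcr_fc)) == sign(seq_lfc); a zero on either
    side counts as discordant. Returns the per-gene map and the overall
    agreement fraction over the shared genes.
    """
    shared = sorted(set(qpcr_fc) & set(seq_lfc))
    if not shared:
        raise ValueError("no shared gene keys between qPCR and sequencing results")
    per_gene = {}
    for g in shared:
        sq = np.sign(np.log2(qpcr_fc[g])) if qpcr_fc[g] > 0 else 0.0
        ss = np.sign(seq_lfc[g])
        per_gene[g] = bool(sq != 0 and ss != 0 and sq == ss)
    fraction = sum(per_gene.values()) / len(shared)
    return {"per_gene": per_gene, "fraction": fraction, "n_genes": len(shared)}
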