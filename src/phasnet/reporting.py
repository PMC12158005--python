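"""Inventory bookkeeping: totals and percentages over annotation counts.

The reporting layer turns a raw inventory of per-class counts (known/novel
miRNAs, 21-/24-nt PHAS loci, triggered loci, trigger miRNAs, model pair
counts) into the derived totals and rounded percentages a study summary
prints.
"""

from __future__ import annotations


def summarize_inventory(inventory: dict) -> dict:
    """Derived totals from a count inventory.

    Required keys: known_mirnas, novel_mirnas, phas21_loci, phas24_loci,
    triggered_phas_loci, trigger_mirnas, model1_pairs, model2_pairs.
    Percentages are rounded to whole percent.
    """
    required = [
        "known_mirnas",
        "novel_mirnas",
        "phas21_loci",
        "phas24_loci",
        "triggered_phas_loci",
        "trigger_mirnas",
        "model1_pairs",
        "model2_pairs",
    ]
    missing = [k for k in required if k not in inventory]
    if missing:
        raise ValueError(f"inventory missing keys: {missing}")
    for k in required:
        if inventory[k] < 0:
            raise ValueError(f"negative count for {k}")

    total_mirnas = inventory["known_mirnas"] + inventory["novel_mirnas"]
    total_phas = inventory["phas21_loci"] + inventory["phas24_loci"]
    if inventory["triggered_phas_loci"] > total_phas:
        raise ValueError("triggered loci exceed total PHAS loci")
    if inventory["trigger_mirnas"] > total_mirnas:
        raise ValueError("trigger miRNAs exceed total miRNAs")
    return {
        "total_mirnas": total_mirnas,
        "total_phas_loci": total_phas,
        "triggered_phas_loci": inventory["triggered_phas_loci"],
        "triggered_phas_pct": round(100 * inventory["triggered_phas_loci"] / total_phas)
        if total_phas
        else 0,
        "trigger_mirna_pct": round(100 * inventory["trigger_mirnas"] / total_mirnas)
        if total_mirnas
        else 0,
        "total_network_pairs": inventory["model1_pairs"] + inventory["model2_pairs"],
    }
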