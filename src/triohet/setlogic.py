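"""Set algebra over DEG calls: SDG, hybrid-specific SDG, and Venn regions.

An SDG ("significant difference gene") is a gene differentially expressed
between the two sampling timepoints within one genotype and environment.
SDG_hp is the hybrid-specific subset: SDGs of the F1 that are SDGs of
neither parent.  SSDG_hp is the environment-stable core: SDG_hp shared by
both growing environments.
"""

from __future__ import annotations

from itertools import product

__all__ = ["sdg", "sdg_hp", "ssdg_hp", "venn_counts"]


def sdg(deg_up: set, deg_down: set) -> set:
    """Union of up- and down-regulated DEGs for one genotype's timepoint
    contrast; the inputs must be disjoint."""
    overlap = set(deg_up) & set(deg_down)
    if overlap:
        raise ValueError(f"up/down DEG sets overlap: {sorted(overlap)[:5]}")
    return set(deg_up) | set(deg_down)


def sdg_hp(sdg_f1: set, sdg_p1: set, sdg_p2: set) -> set:
    """Hybrid-specific SDGs: in the F1 set but in neither parent's."""
    return set(sdg_f1) - (set(sdg_p1) | set(sdg_p2))


def ssdg_hp(sdg_hp_env1: set, sdg_hp_env2: set) -> set:
    """SDG_hp stable across the two environments (intersection)."""
    return set(sdg_hp_env1) & set(sdg_hp_env2)


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Counts of the seven disjoint regions of a three-set Venn diagram.

    ``sets`` maps exactly three names to gene sets; keys of the result are
    the names and their '&'-joined combinations, e.g. ``"A"`` (exclusive to
    A), ``"A&B"`` (A and B but not C), ``"A&B&C"``.  Region counts sum to
    the size of the union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts requires exactly three named sets")
    names = list(sets)
    s = {k: set(v) for k, v in sets.items()}
    out: dict[str, int] = {}
    for membership in product([False, True], repeat=3):
        if not any(membership):
            continue
        region = set.intersection(*(s[n] for n, m in zip(names, membership) if m))
        for n, m in zip(names, membership):
            if not m:
                region = region - s[n]
        out["&".join(n for n, m in zip(names, membership) if m)] = len(region)
    return out
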