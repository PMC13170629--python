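"""Shared builders for NBS-oriented tests."""

from axonet import CohortConfig, generate_cohort, generate_connectomes


def planted_setup(seed, n_nodes=20, edges=((0, 1), (1, 2), (2, 3)),
                  edge_effect=0.025):
    """AN-arm connectomes with a planted NF-L-associated component."""
    cohort = generate_cohort(CohortConfig(seed=seed))
    conns = generate_connectomes(cohort, n_nodes=n_nodes,
                                 planted_components=[list(edges)],
                                 edge_effect=edge_effect, seed=seed + 1)
    an = cohort[cohort["group"] == "AN"].set_index("id")
    mats = {p: conns[p]["FA"] for p in an.index}
    return mats, an
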