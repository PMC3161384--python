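import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def tree_distance_matrix(newick: str):
    """Additive leaf-to-leaf distances of a tree, as a DistanceMatrix."""
    from avbd.trees import DistanceMatrix

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return DistanceMatrix(ids=ids, values=vals)


def leaf_depths(tree: dendropy.Tree) -> dict:
    out = {}
    for lf in tree.leaf_node_iter():
        d, cur = 0.0, lf
        while cur.parent_node is not None:
            d += float(cur.edge.length or 0.0)
            cur = cur.parent_node
        out[lf.taxon.label] = d
    return out


@pytest.fixture(scope="session")
def nine_taxon_tree() -> str:
    return (
        "(((t1:0.2,t2:0.2):0.1,(t3:0.2,t4:0.2):0.1):0.1,"
        "((t5:0.2,t6:0.2):0.1,(t7:0.2,t8:0.2):0.1):0.1,t9:0.3);"
    )


@pytest.fixture(scope="session")
def small_mixture_alignment():
    """6 sequences x 60 codons evolved under a two-class omega mixture."""
    from avbd import EvolConfig, simulate_codon_alignment

    cfg = EvolConfig(
        tree="((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1,(e:0.3,f:0.3):0.1);",
        n_codons=60,
        kappa=2.0,
        class_probs=(0.7, 0.3),
        class_omegas=(0.1, 2.5),
        seed=202,
    )
    return simulate_codon_alignment(cfg)
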