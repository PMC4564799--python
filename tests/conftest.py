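import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plastochron as pc

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle():
    """5 taxa x 2 kb strict-clock fixture with known ground truth."""
    return pc.make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_alignment(tiny_bundle):
    return tiny_bundle.result.alignment


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_alignment(rng, n_taxa, n_cols, gap_prob=0.0):
    chars = list("ACGT")
    rows = []
    for _ in range(n_taxa):
        row = rng.choice(chars, size=n_cols)
        if gap_prob:
            row[rng.random(n_cols) < gap_prob] = "-"
        rows.append("".join(row))
    return pc.Alignment([f"s{i}" for i in range(n_taxa)], rows)


def random_metric_tree(rng, n_taxa):
    """Random unrooted binary tree with uniform(0.05, 1) branch lengths."""
    labels = [f"x{i}" for i in range(n_taxa)]
    tree = pc.simulate_yule_chronogram(n_taxa, 1.0, rng, labels=labels)
    tree = tree.unroot()
    for node in tree.postorder():
        node.age = None
        if node is not tree.root:
            node.length = float(rng.uniform(0.05, 1.0))
    return tree


def tree_path_distances(tree):
    """Pairwise path-length matrix of a tree (pandas DataFrame)."""
    import itertools

    import pandas as pd

    tips = tree.tip_labels()
    tipn = {l: tree.find_tip(l) for l in tips}

    def path(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    D = pd.DataFrame(0.0, index=tips, columns=tips)
    for a, b in itertools.combinations(tips, 2):
        pa, pb = path(tipn[a]), path(tipn[b])
        ids = set(map(id, pa))
        mrca = next(x for x in pb if id(x) in ids)
        d = 0.0
        for x in pa:
            if x is mrca:
                break
            d += x.length or 0.0
        for x in pb:
            if x is mrca:
                break
            d += x.length or 0.0
        D.loc[a, b] = D.loc[b, a] = d
    return D
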