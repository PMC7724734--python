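import numpy as np
import pytest

from cophylo.tree import PhyloTree


def random_binary_tree(rng, n_tips, prefix="t", min_len=0.05, max_len=1.0):
    """Random binary topology with uniform random branch lengths."""
    labels = [f"{prefix}{i}" for i in range(n_tips)]
    parts = {lab: lab for lab in labels}
    avail = list(labels)
    while len(avail) > 1:
        i, j = sorted(rng.choice(len(avail), size=2, replace=False),
                      reverse=True)
        a, b = avail.pop(int(i)), avail.pop(int(j))
        la = rng.uniform(min_len, max_len)
        lb = rng.uniform(min_len, max_len)
        key = a + "|" + b
        parts[key] = f"({parts[a]}:{la:.6f},{parts[b]}:{lb:.6f})"
        avail.append(key)
    return PhyloTree.from_newick(parts[avail[0]] + ";")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def balanced16():
    """16-tip balanced host tree with distinct branch lengths."""
    rng = np.random.default_rng(7)

    def build(tips, depth):
        if len(tips) == 1:
            return f"{tips[0]}:{rng.uniform(0.1, 0.4):.4f}"
        half = len(tips) // 2
        left = build(tips[:half], depth + 1)
        right = build(tips[half:], depth + 1)
        return f"({left},{right}):{rng.uniform(0.1, 0.4):.4f}"

    tips = [f"h{i:02d}" for i in range(16)]
    newick = build(tips, 0)
    # strip the root length
    newick = newick.rsplit(":", 1)[0] + ";"
    return PhyloTree.from_newick(newick)
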