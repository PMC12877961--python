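import numpy as np
import pandas as pd
import pytest

from golgitrace import BinaryMask, SWCTree, Volume


@pytest.fixture
def iso_spacing():
    return (1.0, 1.0, 1.0)


@pytest.fixture
def fmost_spacing():
    return (2.5, 1.0, 1.0)


def make_volume(grid, spacing=(1.0, 1.0, 1.0), bit_depth=8):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return Volume(np.asarray(grid, dtype=dtype), spacing, bit_depth)


def make_mask(grid, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(grid, dtype=bool), spacing)


def make_tree(rows):
    """rows: list of (id, stype, x, y, z, radius, parent)."""
    return SWCTree(pd.DataFrame(rows, columns=["id", "stype", "x", "y", "z", "radius", "parent"]))


def straight_tree(n=11, step=10.0, stype=3):
    """n collinear nodes along +x, ``step`` μm apart, root soma at origin."""
    rows = [(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]
    for i in range(1, n):
        rows.append((i + 1, stype, i * step, 0.0, 0.0, 1.0, i))
    return make_tree(rows)


def y_tree(stem=50.0, arm=50.0):
    """Root soma, a stem along +x, then two arms diverging in ±y."""
    rows = [(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]
    nid = 2
    # stem sampled at 10 μm
    for i in range(1, int(stem // 10) + 1):
        rows.append((nid, 3, i * 10.0, 0.0, 0.0, 1.0, nid - 1))
        nid += 1
    fork = nid - 1
    c = np.sqrt(0.5)
    for sign in (+1, -1):
        prev = fork
        for i in range(1, int(arm // 10) + 1):
            rows.append(
                (nid, 3, stem + c * i * 10.0, sign * c * i * 10.0, 0.0, 1.0, prev)
            )
            prev = nid
            nid += 1
    return make_tree(rows)
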