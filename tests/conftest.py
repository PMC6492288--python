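"""Shared fixtures: the worked-example network and its published matrices."""

import numpy as np
import pytest
from hypothesis import settings

from nmaconnect import paper_network

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def digits(rows: str) -> np.ndarray:
    """Parse a whitespace-separated block of digit strings into an int matrix."""
    return np.array([[int(c) for c in row] for row in rows.split()], dtype=np.int64)


# The 8-treatment worked example: six two-arm trials
# (1-2, 2-3, 2-5, 4-5, 6-7, 7-8), two components {1..5} and {6..8}.
FIG2_A = digits("""
    01000000 10101000 01000000 00001000
    01010000 00000010 00000101 00000010
""")

FIG2_A2 = digits("""
    10101000 03010000 10101000 01010000
    10102000 00000101 00000020 00000101
""")

FIG2_A3 = digits("""
    03010000 30304000 03010000 10102000
    04020000 00000020 00000202 00000020
""")

FIG2_IC3 = digits("""
    11111000 11111000 11111000 11111000
    11111000 00000111 00000111 00000111
""")

FIG2_IC7 = FIG2_IC3  # blocks already saturated at three steps

FIG2_D = digits("""
    01232000 10121000 21032000 32301000
    21210000 00000012 00000101 00000210
""")

# 7-treatment disconnected example: adjacency, indirect connection, and
# the block-collected distance matrix with header order 1 3 6 7 | 2 4 5.
NET1_A = digits("""
    0010011 0001000 1000000 0100100
    0001000 1000001 1000010
""")

NET1_ICM = digits("""
    1010011 0101100 1010011 0101100
    0101100 1010011 1010011
""")

NET1_D_BLOCKED = digits("""
    0111000 1022000 1201000 1210000
    0000012 0000101 0000210
""")
NET1_BLOCK_ORDER = ("1", "3", "6", "7", "2", "4", "5")


@pytest.fixture(scope="session")
def figure2():
    return paper_network("figure2")


@pytest.fixture(scope="session")
def network1():
    return paper_network("network1")


@pytest.fixture(scope="session")
def network2():
    return paper_network("network2")


@pytest.fixture(scope="session")
def network3():
    return paper_network("network3")
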