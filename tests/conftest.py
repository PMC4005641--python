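"""Shared fixtures: the 11-compound printed sequence panel.

The panel is the published motif introduction/removal experiment: a
non-targeting scrambled control (1a) with TGC/TCC written in at
various positions (1b-1f), a doubly motif-bearing ApoC3-targeting
compound (3), and a GR-targeting TCC carrier (4a) with removal
variants (4b-4d).  Six compounds produced liver lesions, five did not.
"""

import pytest

import toxsar as tx

# (id, target, sequence 5'->3', lesions, ALT U/L, AST U/L)
PANEL_ROWS = [
    ("1a", "None", "TAATCGTCGATACC", False, 28.0, 38.0),
    ("1b", "None", "TAATGCTCGATCCC", True, 3369.0, 506.0),
    ("1c", "None", "TAATCCTCGATACC", False, 31.0, 43.0),
    ("1d", "None", "TAATCGTCCATACC", True, 39.0, 57.0),
    ("1e", "None", "TAATCGTGCATACC", False, 39.0, 55.0),
    ("1f", "None", "TAATCGTCGATGCC", True, 48.0, 51.0),
    ("3", "ApoC3", "TCAGTGCATCCTTG", True, None, None),
    ("4a", "GR", "AAGTCTGTTTCCCC", True, None, None),
    ("4b", "GR", "AAGTCTGTTTCACC", False, 110.0, 106.0),
    ("4c", "GR", "AAGTCTGTTACCCC", True, 1943.0, 1311.0),
    ("4d", "GR", "AAGTCTGTTACACC", False, 49.0, 74.0),
]


@pytest.fixture(scope="session")
def panel_dataset() -> tx.Dataset:
    return tx.Dataset(
        [
            tx.GapmerRecord(
                id=i, target=t, bases=s, toxic=lab, alt_u_per_l=alt, ast_u_per_l=ast
            )
            for i, t, s, lab, alt, ast in PANEL_ROWS
        ]
    )


@pytest.fixture()
def panel_table(tmp_path):
    """The panel written as a delimited file, ids non-contiguous as published."""
    path = tmp_path / "panel.csv"
    lines = ["id,target,sequence,label,alt,ast"]
    for i, t, s, lab, alt, ast in PANEL_ROWS:
        label = "Yes" if lab else "No"
        lines.append(
            f"{i},{t},{s},{label},{'' if alt is None else alt},{'' if ast is None else ast}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def catalogue() -> tx.MotifIndex:
    return tx.enumerate_motifs(2, 5)
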