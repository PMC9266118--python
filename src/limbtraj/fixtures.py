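"""Small reference structures used in tests, examples and acceptance checks."""

from __future__ import annotations

from .trajectory import Dendrogram

#: The reference 16-leaf epithelial cherry structure: five cross-condition
#: cherries (EC7–EC15, EC8–EC16, EC2–EC9, EC3–EC10, EC4–EC11), one
#: same-condition cherry per branch side (EC5–EC6 unwounded, EC12–EC13
#: wounded) and singletons EC1 and EC14, arranged in three branches.
#: Under the pairing rule this yields 11 cell types: 5 shared,
#: 3 unwounded-only (EC1, EC5, EC6) and 3 wounded-only (EC12, EC13, EC14).
CHERRY_FIXTURE_NEWICK = (
    "(((EC2|unwounded:0.05,EC9|wounded:0.05):0.25,EC1|unwounded:0.3):0.3,"
    "(((EC3|unwounded:0.05,EC10|wounded:0.05):0.25,"
    "((EC4|unwounded:0.05,EC11|wounded:0.05):0.1,"
    "(EC12|wounded:0.08,EC13|wounded:0.08):0.07):0.15):0.2,"
    "(((EC7|unwounded:0.04,EC15|wounded:0.04):0.08,"
    "(EC8|unwounded:0.05,EC16|wounded:0.05):0.07):0.08,"
    "((EC5|unwounded:0.06,EC6|unwounded:0.06):0.1,EC14|wounded:0.16):0.04):0.3):0.1);"
)


def example_cherry_dendrogram() -> Dendrogram:
    """The 16-leaf epithelial fixture dendrogram (see module constant)."""
    return Dendrogram.from_newick(CHERRY_FIXTURE_NEWICK)
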