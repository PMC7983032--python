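"""Direction/sign consensus and dataset views.

Different resources sometimes disagree on the effect sign of an edge.  The
merged store keeps every per-resource claim; consensus is a majority vote
with explicit contradiction flags, so contradictory knowledge is surfaced
rather than silently resolved.  Dataset views slice the same store by
evidence tags — e.g. only graded TF regulons at high confidence.
"""

import tempfile
from pathlib import Path

from crosstalk_kb import build_knowledgebase, generate_knowledgebase
from crosstalk_kb.network import consensus, dataset_view

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp) / "kb"
    generate_knowledgebase(seed=7, out_dir=base)
    kb = build_knowledgebase(base)

    for interaction in kb.network:
        c = consensus(interaction)
        if c.contradictory_sign:
            claims = [(e.resource, e.sign)
                      for e in interaction.evidences.values()]
            print(f"{interaction.a.id} - {interaction.b.id}: "
                  f"sign claims {claims}")
            print(f"  consensus sign: {c.sign}  "
                  f"(contradictory_sign={c.contradictory_sign})")
    # a tied vote leaves the consensus unset; a 2-vs-1 majority resolves it
    # but keeps the flag raised, so users can apply their own policy.

    print("\ndataset view sizes:")
    for tag in ("omnipath", "ligrecextra", "dorothea", "tf_target"):
        print(f"  {tag:16s} {len(dataset_view(kb.network, {tag})):3d}")
    for level in "ABCD":
        view = dataset_view(kb.network, {"dorothea"}, min_confidence=level)
        print(f"  dorothea <= {level}    {len(view):3d}")
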