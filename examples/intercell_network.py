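"""Transmitter -> receiver network construction.

Joins directed interactions with intercellular role annotations: the source
must carry a transmitter role (ligand, adhesion, secreted enzyme, ...) and
the target a receiver role (receptor, transporter, ...).  The strict profile
used for direct cell-cell contact additionally discards indirect regulator
categories and requires membrane-bound receivers.
"""

import tempfile
from collections import Counter
from pathlib import Path

from crosstalk_kb import build_knowledgebase, generate_knowledgebase
from crosstalk_kb.comm import UC_PROFILE, build_intercell_network

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp) / "kb"
    generate_knowledgebase(seed=7, out_dir=base)
    kb = build_knowledgebase(base)

    edges = build_intercell_network(kb.network, kb.intercell)
    strict = build_intercell_network(kb.network, kb.intercell, UC_PROFILE)
    print(f"transmitter->receiver connections: {len(edges)} "
          f"({len({e.pair() for e in edges})} unique protein pairs)")
    print(f"under the membrane-bound profile : {len(strict)}")

    by_roles = Counter((e.transmitter_category, e.receiver_category)
                       for e in strict)
    print("\nconnections by role pair:")
    for (tx, rx), n in by_roles.most_common():
        print(f"  {tx:16s} -> {rx:12s} {n:3d}")
    example = strict[0]
    print(f"\nexample: {example.transmitter.id} "
          f"({example.transmitter_category}) -> {example.receiver.id} "
          f"({example.receiver_category})")
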