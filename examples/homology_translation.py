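"""Translate the network and PTM sites to another organism.

Protein translation runs accession -> RefSeq -> orthologous RefSeq (same
orthology group, target organism) -> target accession; an interaction
survives when both endpoints translate.  PTM sites additionally go through a
site-level homology table and are re-validated against the target organism's
sequences — a residue that does not match is discarded.
"""

import tempfile
from pathlib import Path

from crosstalk_kb import build_knowledgebase, generate_knowledgebase
from crosstalk_kb.enzyme_ptm import SequenceSet
from crosstalk_kb.homology import (load_site_homology, load_translator,
                                   translate_network, translate_ptms)

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp) / "kb"
    generate_knowledgebase(seed=7, out_dir=base)
    kb = build_knowledgebase(base)

    translator = load_translator(base, source_org=9606, target_org=10090)
    translated, coverage = translate_network(kb.network, translator)
    print(f"network: {len(kb.network)} -> {len(translated)} interactions "
          f"(coverage {coverage:.1%})")
    print(f"dropped: {dict(translated.dropped)}")

    mouse_seqs = SequenceSet.from_fasta(base / "homology" /
                                        "mouse_sequences.fasta")
    survivors = translate_ptms(kb.enzsub, translator,
                               load_site_homology(base), mouse_seqs)
    print(f"\nenzyme-PTM: {len(kb.enzsub)} -> {len(survivors)} sites")
    print(f"dropped: {dict(survivors.dropped)}, "
          f"residue re-validation rejections: {dict(survivors.rejected)}")
    for rec in list(survivors)[:3]:
        print(f"  {rec.enzyme.id} -> {rec.substrate.id} "
              f"{rec.residue_letter}{rec.position} ({rec.modification})")
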