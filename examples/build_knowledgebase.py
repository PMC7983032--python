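"""Build the five databases from a synthetic resource directory.

Generates a small knowledge base (resource files in every supported format,
with planted ground truth), builds the network / enzyme-PTM / complex /
annotation / intercell databases, and prints their sizes.  The printed counts
equal the generator manifest's planted unique-key counts — merging is exact
deduplication, not approximation.
"""

import tempfile
from pathlib import Path

from crosstalk_kb import build_knowledgebase, generate_knowledgebase
from crosstalk_kb.build import export_all

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp) / "kb"
    manifest = generate_knowledgebase(seed=7, out_dir=base)
    kb = build_knowledgebase(base)

    print(f"interactions : {len(kb.network):4d} "
          f"(manifest: {manifest['network']['total_unique']})")
    print(f"enzyme-PTM   : {len(kb.enzsub):4d} "
          f"(manifest: {manifest['enzsub']['unique_valid']}; "
          f"rejected residues: {dict(kb.enzsub.rejected)})")
    print(f"complexes    : {len(kb.complexes):4d} "
          f"(manifest: {manifest['complexes']['n_identities']})")
    print(f"annotations  : {len(kb.annotations):4d} long-format rows")
    print(f"intercell    : {len(kb.intercell.composite_categories())} "
          f"composite categories")

    paths = export_all(kb, Path(tmp) / "export")
    print("\nfirst lines of the interaction export:")
    for line in paths["interactions.tsv"].read_text().splitlines()[:4]:
        print(" ", line[:100])
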