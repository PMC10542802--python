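"""Regenerate the packaged reference fixture (gene_map.tsv + synthetic FASTA).

The fixture is deterministic (fixed build seed); running this script is
only needed after editing the gene table or the sequence builder.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from hetburden._refbuild import write_fixture  # noqa: E402

if __name__ == "__main__":
    data_dir = pathlib.Path(__file__).resolve().parents[1] / "src" / "hetburden" / "data"
    write_fixture(data_dir)
    print(f"wrote fixture to {data_dir}")
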