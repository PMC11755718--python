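"""Fetch the published reference data used by the reference-number tests.

Downloads (network required):
  * PDB entry 4RHW (Apaf-1 CARD / caspase-9 CARD assembly) -> data/reference/4rhw.pdb
  * chain sequences of the caspase-9 CARD (4RHW chain E) and the RAIDD CARD
    (PDB 3CRD chain A) -> data/reference/c9card.fasta, rdcard.fasta
The deposited MD trajectories and docked poses (Zenodo record 13736242) are
large; download them manually and unpack multi-model PDB trajectories as
data/reference/zenodo/native_md{1,2,3}.pdb if the optional trajectory checks
are wanted.
"""

import sys
import urllib.request
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "data" / "reference"


def fetch(url: str) -> bytes:
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as fh:
        return fh.read()


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    pdb = fetch("https://files.rcsb.org/download/4RHW.pdb")
    (OUT / "4rhw.pdb").write_bytes(pdb)

    # chain sequences from the entries' FASTA records
    fasta_4rhw = fetch("https://www.rcsb.org/fasta/entry/4RHW").decode()
    fasta_3crd = fetch("https://www.rcsb.org/fasta/entry/3CRD").decode()

    def first_record(text: str) -> str:
        blocks = [b for b in text.split(">") if b.strip()]
        header, *lines = blocks[0].splitlines()
        return f">{header}\n" + "".join(lines) + "\n"

    (OUT / "c9card.fasta").write_text(_chain_record(fasta_4rhw, "E")
                                      or first_record(fasta_4rhw))
    (OUT / "rdcard.fasta").write_text(_chain_record(fasta_3crd, "A")
                                      or first_record(fasta_3crd))
    print(f"reference data written to {OUT}")
    return 0


def _chain_record(fasta_text: str, chain: str) -> str | None:
    for block in fasta_text.split(">"):
        if not block.strip():
            continue
        header, *lines = block.splitlines()
        # RCSB headers look like "4RHW_1|Chains A, B, E|..."
        if "|" in header:
            chains_field = header.split("|")[1].replace("Chains", "").replace(
                "Chain", "")
            chains = {c.strip() for part in chains_field.split(",")
                      for c in part.split()}
            if chain in chains:
                return f">{header}\n" + "".join(lines) + "\n"
    return None


if __name__ == "__main__":
    sys.exit(main())
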