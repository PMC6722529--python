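"""Composition and RSCU of a synthetic GC-rich gene set.

Builds a small coat-protein-like set of coding sequences, then prints the
mean nucleotide composition and the most-preferred codon of a few families.
"""

import tempfile

import numpy as np

from codonuse import (
    composition_profile,
    count_codons,
    mean_rscu,
    preferred_codons,
    read_fasta,
    rscu,
)
from codonuse.synthetic import cp_like_fixture

with tempfile.TemporaryDirectory() as tmp:
    fasta, meta, truth = cp_like_fixture(seed=7, out_dir=tmp)
    seqs = read_fasta(fasta)

profiles = [composition_profile(s) for s in seqs]
print(f"{len(seqs)} sequences, {len(seqs[0])} codons each")
print(f"mean GC%   = {np.mean([p.gc for p in profiles]):.2f}  "
      "(GC-rich regime, like a carlavirus coat-protein gene)")
print(f"mean GC3s% = {np.mean([p.gc3s for p in profiles]):.2f}  "
      "(third-position GC, the mutational readout)")

group = mean_rscu([rscu(count_codons(s)) for s in seqs])
marks = preferred_codons(group)
print("\npreferred codon per family (first five, RSCU of the winner):")
for aa in sorted(marks)[:5]:
    codon, tie = marks[aa]
    print(f"  {aa}: {codon.replace('T', 'U')}  "
          f"RSCU = {group.values[codon]:.2f}{'  (tie)' if tie else ''}")
print("\nRSCU > 1 means the codon is used more than expected under "
      "equal synonymous usage.")
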