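Reference data files (abcg2_human.fasta, abcg5_human.fasta,
abcg8_human.fasta, 5do7.pdb) are downloaded here by
scripts/fetch_data.py on a networked machine. They are public data
from UniProt and the RCSB PDB and are not redistributed with the
source tree.
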