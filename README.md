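# pocketsim

Pharmacological mapping of protein binding pockets from ligand contact
patterns. Given a set of protein–ligand complexes (PDB), a master multiple
sequence alignment of the catalytic domains, and a site definition
(cofactor vs substrate), `pocketsim`:

1. loads and validates each complex (one chain, heavy atoms, selected
   ligand groups, highest-occupancy altlocs);
2. detects explicit protein–ligand interactions (H-bond donor/acceptor,
   ionic, surface, arene) and encodes them as binary fingerprints per
   alignment column, with Tanimoto comparison and summary tables;
3. computes distance-ramp contact-strength profiles per target (soft
   contact score 1 below 3.23 Å, 0 above 4.63 Å, linear in between;
   per-residue totals aggregated over complexes in ensemble mode);
4. propagates the profiles through the master alignment using normalized
   Gonnet residue similarities, producing per-profile raw score matrices,
   Z-scored matrices, their average, a min-max-normalized similarity
   matrix in [0, 1], and the complementary distance matrix;
5. ranks pharmacological neighbors per target and builds average-linkage
   (UPGMA) trees with Newick export.

A synthetic-fixture module generates toy complexes with prescribed
geometry (plus their analytically expected contact vectors and
interaction bits) and alignments with planted binding-site neighbors, so
the whole pipeline is testable offline.

## CLI

The pipeline is driven by a YAML config pointing at a manifest TSV
(columns: `complex_id  path  chain  target  site  ligand_selector
alignment_row`) and the master alignment (Clustal or aligned FASTA):

```yaml
manifest: manifest.tsv
alignment: master.fasta
output_dir: out
seed: 1
ensemble_mode: max        # or mean
identity_floor: 0.60      # structure/row alignment guard
```

```bash
pocketsim all config.yaml      # full pipeline
pocketsim load config.yaml     # validate manifest, report atom counts
pocketsim -v all config.yaml   # INFO logging incl. dropped-residue counts
```

Per site the output bundle contains fingerprints and interaction
summaries, contact profiles, every score-matrix stage as CSV, neighbor
rankings, two Newick trees (fingerprint Tanimoto tree over complexes,
contact-profile UPGMA tree over all sequences), and a
`run_metadata.json` echoing every threshold/mode decision plus a config
hash. Exit codes: 0 success, 2 config error, 3 stage failure.

## Library

```python
import pocketsim as ps

cplx = ps.load_complex("5hyn.pdb", "A", ["SAH"], site="cofactor")
aln = ps.read_alignment("mt_domains.fasta")
amap = ps.map_structure_to_columns(cplx, aln, "EZH2")
vec = ps.complex_contact_vector(cplx, amap)
profile = ps.ensemble_profile([vec], "EZH2", "cofactor")
stages = ps.score_matrix(aln, [profile])
ps.rank_neighbors(stages.normalized, "EZH2", k=5)
```

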