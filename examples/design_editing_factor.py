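"""Design a synthetic PLS-class editing factor against a target RNA.

Builds position-specific consensus scaffolds from a (simulated) collection
of aligned PPR motifs, then programs the 5th/last residues of each
contacting motif with the PPR code so the factor binds a chosen 12-nt
target.  Prints the programmed motif array.
"""

from ppredit import (
    build_consensus,
    canonical_arrangement,
    design_factor,
    simulate_motif_collection,
)
from ppredit.defaults import default_code_table

TARGET = "GAUUACAGGAUC"  # one base per contacting motif, 5'->3'

# A motif collection would normally come from aligned FASTA
# (ppredit.read_motif_collection); here we simulate one per scaffold slot.
scaffold = []
for i, (motif_type, triplet) in enumerate(canonical_arrangement()):
    motifs = simulate_motif_collection(
        120, "VVTYNTLIDGLCKAGKVDEALELFEEMKEKGIKPD", divergence=0.25, seed=i
    )
    scaffold.append((motif_type, triplet, build_consensus(motifs)))

factor = design_factor(TARGET, scaffold, default_code_table(),
                       name="dsn3PLS-DYW", cap="MGNS")

print(f"{factor.name}: cap {factor.cap}, {len(factor.motifs)} motifs, "
      f"{factor.n_contacting} contacting RNA")
for motif, base in zip(factor.contacting_motifs, TARGET):
    print(f"  {motif.motif_type.value:>3}  5th/last = {motif.fifth}/{motif.last}"
          f"  -> {base}")
print("Each contacting motif's residue pair is the code-table entry for its")
print("aligned target base; the edited C sits 4 nt 3' of the S2-aligned base.")
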