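"""Build couplons from a regulatory network.

Generates a small synthetic genome and TRN, then intersects each
NAP/global-TF regulon with each sigma-factor regulon.  The printed grid
holds couplon sizes: how many genes sit under joint control of each
regulator pair.
"""
import couplonscan as cs

spec = cs.SimulationSpec(
    seed=1,
    n_genes=500,
    chromosome_length=500_000,
    cluster_halfwidth=25_000,
    regulators=(
        cs.RegulatorSpec("RpoD", "sigma", 150, program="early"),
        cs.RegulatorSpec("RpoS", "sigma", 80, program="late"),
        cs.RegulatorSpec("FIS", "NAP", 60, program="early",
                         overlaps={"RpoD": 0.5, "RpoS": 0.2}),
        cs.RegulatorSpec("CRP", "globalTF", 90, program="early",
                         overlaps={"RpoD": 0.4}),
    ),
)
ann, _, rs, _ = cs.generate_dataset(spec)

table = cs.couplon_table(rs, ["FIS", "CRP"], ["RpoD", "RpoS"])
print("Couplon sizes (rows: NAP/global TF, columns: sigma factor):")
print(table.to_string())

c = cs.build_couplon(rs["FIS"], rs["RpoS"])
print(
    f"\nFIS/RpoS couplon: {c.size} genes shared between the FIS regulon "
    f"({c.parent_sizes[0]} genes) and the RpoS regulon ({c.parent_sizes[1]} genes)."
)
print("Each count is the plain set intersection of the two regulons'")
print("target genes, ignoring activation/repression sign.")
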