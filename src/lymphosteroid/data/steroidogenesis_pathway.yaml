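# Default steroidogenesis pathway: ordered metabolite steps from cholesterol
# acquisition through mitochondrial import to pregnenolone and the enzymes
# immediately downstream.  Each step lists the gene symbols whose expression
# is required to produce the step's metabolite; any_of marks steps served by
# redundant routes or paralogous transporters (one detected member suffices).
name: steroidogenesis
steps:
  - metabolite: cholesterol
    # de novo synthesis (Hmgcr/Hmgcs1/Sqle/Dhcr7) or receptor-mediated uptake
    # (Ldlr, Scarb1): either route supplies substrate
    required_genes: [Hmgcr, Hmgcs1, Sqle, Dhcr7, Ldlr, Scarb1]
    any_of: true
  - metabolite: outer-membrane cholesterol
    # voltage-dependent anion channel paralogs of the transduceosome
    required_genes: [Vdac1, Vdac2, Vdac3]
    any_of: true
  - metabolite: matrix cholesterol
    # translocator protein / StAR-domain transfer proteins
    required_genes: [Tspo, Stard3, Stard5]
    any_of: true
  - metabolite: pregnenolone
    # cholesterol side-chain cleavage: the rate-limiting committed step
    required_genes: [Cyp11a1]
    any_of: false
  - metabolite: downstream steroids
    # first enzymes past pregnenolone (17-hydroxylase / 3beta-HSD)
    required_genes: [Cyp17a1, Hsd3b1]
    any_of: true
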