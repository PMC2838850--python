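"""Fixed filler-token vocabulary for synthetic record text."""

FILLER_WORDS = (
    "cell",
    "protein",
    "receptor",
    "signal",
    "membrane",
    "nucleus",
    "pathway",
    "binding",
    "enzyme",
    "kinase",
    "expression",
    "transcript",
    "domain",
    "complex",
    "tissue",
    "plasma",
    "serum",
    "antibody",
    "antigen",
    "ligand",
    "mutation",
    "variant",
    "allele",
    "locus",
    "marker",
    "strain",
    "model",
    "study",
    "analysis",
    "result",
    "activation",
    "inhibition",
    "regulation",
    "response",
    "induction",
    "secretion",
    "adhesion",
    "migration",
    "proliferation",
    "apoptosis",
    "cytokine",
    "chemokine",
    "interleukin",
    "macrophage",
    "lymphocyte",
    "neutrophil",
    "monocyte",
    "fibroblast",
    "epithelium",
    "endothelium",
    "cartilage",
    "synovium",
    "tendon",
    "muscle",
    "skeletal",
    "vascular",
    "neural",
    "hepatic",
    "renal",
    "dermal",
    "acute",
    "chronic",
    "systemic",
    "localized",
    "severe",
    "mild",
    "progressive",
    "transient",
    "persistent",
    "recurrent",
    "patient",
    "cohort",
    "control",
    "sample",
    "assay",
    "measurement",
    "concentration",
    "gradient",
    "buffer",
    "reagent",
    "homolog",
    "ortholog",
    "paralog",
    "sequence",
    "genome",
    "chromosome",
    "plasmid",
    "vector",
    "clone",
    "fragment",
    "upstream",
    "downstream",
    "promoter",
    "enhancer",
    "intron",
    "exon",
    "codon",
    "peptide",
    "residue",
    "motif",
    "alpha",
    "beta",
    "gamma",
    "delta",
    "epsilon",
    "kappa",
    "sigma",
    "factor",
    "subunit",
    "isoform",
    "growth",
    "differentiation",
    "development",
    "morphogenesis",
    "repair",
    "remodeling",
    "turnover",
    "synthesis",
    "degradation",
    "clearance",
    "oxidative",
    "metabolic",
    "synaptic",
    "hormonal",
    "enzymatic",
    "structural",
    "functional",
    "molecular",
    "cellular",
    "genetic",
    "increase",
    "decrease",
    "elevated",
    "reduced",
    "normal",
    "abnormal",
    "deficient",
    "excessive",
    "impaired",
    "enhanced",
    "mouse",
    "human",
    "bovine",
    "porcine",
    "canine",
    "murine",
    "primate",
    "rodent",
    "mammalian",
    "vertebrate",
    "blood",
    "bone",
    "joint",
    "liver",
    "kidney",
    "spleen",
    "thymus",
    "marrow",
    "cortex",
    "node",
)
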