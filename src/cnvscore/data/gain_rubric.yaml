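# Default scoring table for copy-number GAIN evaluation.
# Encoded from the 2020 ACMG/ClinGen technical standard for CNV
# interpretation (Riggs et al. 2020, Genet Med 22:245-257). Every number
# here is editable config, not engine logic.
dosage_type: gain
thresholds:
  p_min: 0.99
  lp_min: 0.90
  lb_max: -0.90
  b_max: -0.99
gene_count_bins:
  - {code: 3A, max_count: 34}
  - {code: 3B, max_count: 49}
  - {code: 3C, max_count: null}
# 2J and 2K are mutually exclusive readings of the same breakpoint
# observation and may never be applied together.
exclusive_groups:
  - [2J, 2K]
section_caps: {}
categories:
  - code: 1A
    section: 1
    role: content
    default: 0.0
    min: 0.0
    max: 0.0
    description: Overlaps at least one protein-coding gene or known functionally important element; continue evaluation.
  - code: 1B
    section: 1
    role: no_content
    default: -0.60
    min: -0.60
    max: -0.60
    description: Contains no protein-coding genes and no known functionally important elements.
  - code: 2A
    section: 2
    role: dosage_full_overlap
    default: 1.00
    min: 1.00
    max: 1.00
    description: Complete containment of an established triplosensitive gene or region.
  - code: 2B
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Partial overlap of an established triplosensitive region; continue evaluation of the involved content.
  - code: 2C
    section: 2
    default: -1.00
    min: -1.00
    max: -1.00
    description: Identical in gene content to an established benign copy-number gain.
  - code: 2D
    section: 2
    role: benign_containment
    default: -1.00
    min: -1.00
    max: -1.00
    description: Smaller than an established benign gain with breakpoints that do not interrupt protein-coding genes.
  - code: 2E
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Larger than an established benign gain without additional protein-coding genes.
  - code: 2F
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Overlaps an established benign gain but includes additional genomic material.
  - code: 2G
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Overlaps an established haploinsufficient gene or region; continue evaluation.
  - code: 2H
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: An established haploinsufficient gene is completely contained within the gain without breakpoint disruption.
  - code: 2I
    section: 2
    default: 0.0
    min: 0.0
    max: 0.90
    description: Both breakpoints within the same gene (intragenic duplication); weight per predicted coding impact.
  - code: 2J
    section: 2
    role: gain_spans_hi
    default: 0.0
    min: 0.0
    max: 0.0
    description: Breakpoint observation at an established haploinsufficient gene read as non-disruptive or with unknown/inconsistent patient phenotype.
  - code: 2K
    section: 2
    role: gain_breakpoint_in_hi
    default: 0.45
    min: 0.45
    max: 0.45
    description: One breakpoint within an established haploinsufficient gene with a highly specific consistent patient phenotype.
  - code: 2L
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: One breakpoint within a gene of no established dosage sensitivity; continue evaluation.
  - code: 3A
    section: 3
    default: 0.0
    min: 0.0
    max: 0.0
    description: 0-34 protein-coding genes within the gain.
  - code: 3B
    section: 3
    default: 0.45
    min: 0.45
    max: 0.45
    description: 35-49 protein-coding genes within the gain.
  - code: 3C
    section: 3
    default: 0.90
    min: 0.90
    max: 0.90
    description: 50 or more protein-coding genes within the gain.
  - code: 4A
    section: 4
    default: 0.45
    min: 0.0
    max: 0.90
    description: Reported proband with a highly specific consistent phenotype and confirmed de novo occurrence.
  - code: 4B
    section: 4
    default: 0.30
    min: 0.0
    max: 0.45
    description: Reported proband with a consistent phenotype and assumed de novo occurrence.
  - code: 4C
    section: 4
    default: 0.15
    min: 0.0
    max: 0.45
    description: Reported proband with a specific consistent phenotype, inheritance unknown or inherited from an affected parent.
  - code: 4D
    section: 4
    default: 0.10
    min: 0.0
    max: 0.30
    description: Reported proband with a nonspecific but consistent phenotype and confirmed de novo occurrence.
  - code: 4E
    section: 4
    default: 0.10
    min: 0.0
    max: 0.15
    description: Reported proband with a nonspecific phenotype and unknown inheritance.
  - code: 4F
    section: 4
    default: -0.15
    min: -0.45
    max: 0.0
    description: Reported case with an overlapping variant and a phenotype inconsistent with the gene or region.
  - code: 4G
    section: 4
    default: -0.15
    min: -0.45
    max: 0.0
    description: Overlapping variant reported in an apparently unaffected individual.
  - code: 4H
    section: 4
    default: -0.15
    min: -0.30
    max: 0.0
    description: Inheritance pattern in reported families inconsistent with pathogenicity.
  - code: 4I
    section: 4
    default: 0.15
    min: 0.0
    max: 0.45
    description: Segregation among 3-4 observed informative meioses in reported families.
  - code: 4J
    section: 4
    default: 0.30
    min: 0.0
    max: 0.45
    description: Segregation among 5-6 observed informative meioses in reported families.
  - code: 4K
    section: 4
    default: 0.45
    min: 0.0
    max: 0.45
    description: Segregation among 7 or more observed informative meioses in reported families.
  - code: 4L
    section: 4
    default: 0.45
    min: 0.0
    max: 0.45
    description: Statistically significant excess among cases versus controls.
  - code: 4M
    section: 4
    default: -0.30
    min: -0.45
    max: 0.0
    description: No statistically significant difference between cases and controls.
  - code: 4N
    section: 4
    default: -0.90
    min: -0.90
    max: 0.0
    description: Statistically significant excess among controls versus cases.
  - code: 4O
    section: 4
    default: -1.00
    min: -1.00
    max: 0.0
    description: Overlap with a common population variant (frequency above 1%) or otherwise well-represented in population datasets.
  - code: 5A
    section: 5
    default: 0.0
    min: 0.0
    max: 0.45
    description: Constitutional de novo occurrence in the patient under investigation; weight per phenotype specificity.
  - code: 5B
    section: 5
    default: 0.30
    min: 0.0
    max: 0.45
    description: Inherited from an apparently affected parent, consistent specific phenotype in the patient.
  - code: 5C
    section: 5
    default: 0.15
    min: 0.0
    max: 0.30
    description: Additional affected family members carry the variant with consistent phenotype.
  - code: 5D
    section: 5
    default: -0.30
    min: -0.45
    max: 0.0
    description: Non-segregation with phenotype in the family under investigation.
  - code: 5E
    section: 5
    default: -0.15
    min: -0.45
    max: 0.0
    description: Inherited from an apparently unaffected parent.
  - code: 5F
    section: 5
    default: 0.0
    min: -0.45
    max: 0.45
    description: Other family-history evidence not captured by the categories above.
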