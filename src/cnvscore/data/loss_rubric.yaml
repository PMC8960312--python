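# Default scoring table for copy-number LOSS evaluation.
# Encoded from the 2020 ACMG/ClinGen technical standard for CNV
# interpretation (Riggs et al. 2020, Genet Med 22:245-257). Every number
# here is editable config, not engine logic.
dosage_type: loss
thresholds:
  p_min: 0.99
  lp_min: 0.90
  lb_max: -0.90
  b_max: -0.99
# Protein-coding gene count -> Section 3 category (upper bounds inclusive;
# the last bin is open-ended).
gene_count_bins:
  - {code: 3A, max_count: 24}
  - {code: 3B, max_count: 34}
  - {code: 3C, max_count: null}
# Categories that may never be applied together on one worksheet.
exclusive_groups: []
# Optional per-section caps on summed contribution; empty = no caps.
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
    description: Complete overlap of an established haploinsufficient gene or region.
  - code: 2B
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Partial overlap of an established haploinsufficient region; continue evaluation of the involved content.
  - code: 2C-1
    section: 2
    default: 0.90
    min: 0.45
    max: 1.00
    description: Partial overlap of the 5' end of an established haploinsufficient gene with coding sequence involved.
  - code: 2C-2
    section: 2
    default: 0.0
    min: 0.0
    max: 0.45
    description: Partial overlap of the 5' end of an established haploinsufficient gene, only the 5' UTR involved.
  - code: 2D-1
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Partial overlap of the 3' end, only the 3' UTR involved.
  - code: 2D-2
    section: 2
    default: 0.90
    min: 0.45
    max: 0.90
    description: Partial overlap of the 3' end limited to the last exon, with established pathogenic variants reported in that exon.
  - code: 2D-3
    section: 2
    default: 0.30
    min: 0.0
    max: 0.45
    description: Partial overlap of the 3' end limited to the last exon, without established pathogenic variants in that exon.
  - code: 2D-4
    section: 2
    default: 0.90
    min: 0.45
    max: 1.00
    description: Partial overlap of the 3' end including exons beyond the last one.
  - code: 2E
    section: 2
    default: 0.0
    min: 0.0
    max: 0.90
    description: Both breakpoints within the same gene (intragenic deletion); weight per predicted coding impact.
  - code: 2F
    section: 2
    role: benign_containment
    default: -1.00
    min: -1.00
    max: -1.00
    description: Completely contained within an established benign region.
  - code: 2G
    section: 2
    default: 0.0
    min: 0.0
    max: 0.0
    description: Overlaps an established benign region but includes additional genomic material.
  - code: 2H
    section: 2
    default: 0.15
    min: 0.0
    max: 0.15
    description: Two or more haploinsufficiency predictors suggest at least one overlapped gene is dosage-sensitive.
  - code: 3A
    section: 3
    default: 0.0
    min: 0.0
    max: 0.0
    description: 0-24 protein-coding genes within the loss.
  - code: 3B
    section: 3
    default: 0.45
    min: 0.45
    max: 0.45
    description: 25-34 protein-coding genes within the loss.
  - code: 3C
    section: 3
    default: 0.90
    min: 0.90
    max: 0.90
    description: 35 or more protein-coding genes within the loss.
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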