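Place the externally distributed harmonized per-SNP instrument tables
here to enable the published-estimate replication (acceptance targets
t1-t9 and tests/test_acceptance.py::TestCriterion4PublishedEstimates).

Expected files (tab-delimited, one per exposure):

    fgf23.tsv   (7 SNPs)
    gdf15.tsv   (5 SNPs)
    igf1.tsv    (318 SNPs)
    igfbp3.tsv  (4 SNPs)
    vegf.tsv    (10 SNPs)

Required columns:

    SNP            rsID
    beta_exposure  per-allele effect on the exposure (SD units)
    se_exposure    its standard error
    beta_outcome   per-allele effect on the outcome (log odds ratio)
    se_outcome     its standard error (log-OR scale)

Exposure and outcome effects must already refer to the same effect
allele (the tables as distributed are harmonized). These tables are not
bundled: they exist only as journal supplementary material and cannot be
reconstructed from this repository.
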