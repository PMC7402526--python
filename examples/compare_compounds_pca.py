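"""Position compounds against each other by PCA of their Emax_T profiles.

Embeds the eight reference compounds in the 13-dimensional space of
per-cell-type Emax_T values and runs mean-centered, unscaled PCA.  The
taxanes (strong granulocyte/erythroid cell killing) separate from the CDK
inhibitors and the thalidomide negative control along the first component.
"""

from hemodecon import (
    REFERENCE_DRUGS,
    assemble_parameter_matrix,
    reference_drug,
    run_pca,
)

fits = {name: reference_drug(name) for name in REFERENCE_DRUGS}
matrix = assemble_parameter_matrix(fits, "emaxT")
result = run_pca(matrix)

print("Percent variance per component:")
print(result.variance_pct.round(1).to_string())
print("\nCompound scores on the first two components:")
print(result.scores[["PC1", "PC2"]].round(2).to_string())
print("\nVariables most correlated (|r| > 0.1) with PC1:")
strong = result.correlations["PC1"].abs() > 0.1
print(result.correlations.loc[strong, "PC1"].round(2).to_string())
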