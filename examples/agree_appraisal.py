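"""Appraise the nine AECOPD guidelines with AGREE II standardized scores.

Uses the published three-appraiser item means bundled in cosel.datasets,
computes the six standardized domain scores per document, the cross-document
domain means, and the A/B/C recommendation level.
"""

from cosel import agree, datasets as ds

matrices = [
    agree.AppraisalMatrix.from_item_means(doc, ds.GUIDELINE_ITEM_MEANS[doc],
                                          ds.N_APPRAISERS)
    for doc in ds.GUIDELINE_DOCUMENTS
]
table = agree.appraise_documents(matrices)
print(table.drop(columns="icc").to_string(index=False))
print("\nDomain scores are 100*(obtained-min)/(max-min) on the 1-7 item scale;")
print("grade A needs every domain >= 60%, grade C fewer than 3 domains >= 30%.")
print("ICC is unavailable here because only item means (not per-rater scores)")
print("were published.")
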