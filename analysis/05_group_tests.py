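"""Reproduce the clinical-table t/F comparisons from per-stratum summaries
and the binormal single-cohort AUCs of the tissue arms."""
from mirmeta import (anova_oneway_from_summary, binormal_auc, load_fixture,
                     pooled_t, published, welch_t)

groups = {f"table{i}": load_fixture(f"table{i}_groups") for i in (1, 2, 3, 4)}

def rows(table, variable):
    return [r for r in groups[table] if r.variable == variable]

checks = [
    ("table1", "Tumor size", "welch"),
    ("table2", "Tumor size", "welch"),
    ("table2", "Age (years)", "welch"),
    ("table3", "Tissue", "pooled"),
    ("table4", "Tissue", "welch"),
    ("table1", "Pathological grading", "anova"),
    ("table2", "Pathological grading", "anova"),
]
for table, variable, method in checks:
    rs = rows(table, variable)
    if method == "anova":
        res = anova_oneway_from_summary(rs)
        print(f"{table} {variable:22s} F = {res.statistic:7.3f} "
              f"(df {res.df1:.0f}/{res.df2:.0f})  p = {res.p_value:.3g}")
    else:
        fn = welch_t if method == "welch" else pooled_t
        res = fn(rs[0], rs[1])
        print(f"{table} {variable:22s} t = {res.statistic:7.3f} "
              f"({res.method}, df {res.df1:.1f})  p = {res.p_value:.3g}")

print("\nBinormal AUC of the cohort tissue arms:")
for study in (published.qpcr_tissue_summary(), published.seq_tissue_summary()):
    print(f"  {study.study_id:13s} AUC = {binormal_auc(study):.3f}")
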