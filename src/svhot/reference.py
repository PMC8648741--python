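"""Published reference behaviours from the original 112-sample LMS WGS
cohort (ICGC) and the TCGA Pan-Cancer reanalysis.

These numbers depend on datasets that are not packaged; they are recorded
here as reference points for users applying the toolkit to real cohorts,
never asserted as desk-reproducible results.
"""

LMS_COHORT_REFERENCE = {
    "desk_reproducible": False,
    "n_samples": 112,
    "n_breakpoints": 24_870,
    "n_sv": 12_435,
    "fraction_intra": 0.674,
    "tbpc": {"min": 26, "max": 1200, "mean": 222.1, "median": 181},
    "itrac_thresholds": (0.99, 2.29),
    "iracin_thresholds": (0.74, 1.30),
    "itrac_logrank_p": 3.08e-5,
    "iracin_logrank_p": 4.13e-5,
    "magic_logrank_p": 8.75e-8,
    "magic_median_mfs_years": {"High": 1.8, "Low": 10.5},
    "chemo_low_itrac_hr": {"hr": 4.47, "ci": (1.65, 12.08), "p": 0.0032},
}

PAN_CANCER_REFERENCE = {
    "desk_reproducible": False,
    "n_groups_best": 5,
    "logrank_p": 6.9e-10,
    "max_hr": 4.75,
    "max_hr_p": 3.42e-9,
    "thresholds": (0.14, 0.45, 0.67, 0.86),
}
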