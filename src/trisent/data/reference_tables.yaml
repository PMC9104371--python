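# Published results of the lockdown-survey sentiment study this package
# models, transcribed as fixtures so verification needs no data access.
#
# Confusion matrices: rows = predicted, columns = real,
# class order (negative, neutral, positive).
#
# expected_metrics rows follow the published table's row labels.  Against
# the printed matrix orientation, the published "weighted_precision" row
# matches support-weighted one-vs-all RECALL (identically trace/total) and
# "weighted_recall" matches support-weighted one-vs-all PRECISION; the
# verification code maps the rows accordingly.  "accuracy" cells 88.88 and
# 72.85 are truncated rather than rounded (exact 88.889 / 72.857).

confusion_matrices:
  mlp_students:
    - [165, 8, 2]
    - [1, 22, 6]
    - [6, 2, 13]
  mlp_staff:
    - [70, 3, 5]
    - [0, 22, 4]
    - [1, 3, 32]
  svm_students:
    - [160, 11, 3]
    - [8, 18, 9]
    - [4, 3, 9]
  svm_staff:
    - [66, 5, 11]
    - [3, 15, 9]
    - [2, 8, 21]

expected_metrics:
  mlp_students:
    weighted_accuracy: 92.49
    weighted_precision: 88.89
    weighted_recall: 88.64
    weighted_f1: 88.74
    accuracy: 88.88
  mlp_staff:
    weighted_accuracy: 92.59
    weighted_precision: 88.57
    weighted_recall: 88.47
    weighted_f1: 88.29
    accuracy: 88.57
  svm_students:
    weighted_accuracy: 88.42
    weighted_precision: 83.11
    weighted_recall: 82.86
    weighted_f1: 82.88
    accuracy: 83.11
  svm_staff:
    weighted_accuracy: 82.55
    weighted_precision: 72.86
    weighted_recall: 71.77
    weighted_f1: 71.75
    accuracy: 72.85

# Mean decision thresholds after 5-fold cross-validation (outer limits
# fixed at -1 and +1).
threshold_presets:
  mlp-students: {t_pos_neu: 0.49, t_neu_neg: 0.22}
  mlp-staff: {t_pos_neu: 0.52, t_neu_neg: 0.38}
  svm-students: {t_pos_neu: 0.41, t_neu_neg: 0.24}
  svm-staff: {t_pos_neu: 0.42, t_neu_neg: 0.26}

# Survey sample sizes by country and role.
sample_sizes:
  students: {Spain: 106, Colombia: 119, subtotal: 225}
  staff: {Spain: 82, Colombia: 58, subtotal: 140}
  total: 365
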