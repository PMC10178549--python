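"""Published per-class evaluation rows used as internal-consistency fixtures.

Each row: (table, config, class_code, support, P, R, F1, E) — precision,
recall, F1 and classification error as percentages, exactly as printed in
the reference origin-classification experiments (test-set tables for the
RF/SVM/CNN models and the online-device validation). The fixtures assert
only the relations that the metric definitions force between printed cells:
F1 = 2PR/(P+R) and E = 100 - R, both to 2 decimals.
"""

# (table, preprocessing+selection, class, support, P, R, F1, E)
ROWS = [
    # random-forest test-set results
    ("rf", "sg+spa", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("rf", "sg+spa", 1, 18, 94.44, 94.44, 94.44, 5.56),
    ("rf", "sg+spa", 2, 29, 96.55, 96.55, 96.55, 3.45),
    ("rf", "snv+spa", 0, 32, 100.00, 96.88, 98.42, 3.12),
    ("rf", "snv+spa", 1, 18, 85.00, 94.44, 89.47, 5.56),
    ("rf", "snv+spa", 2, 29, 96.43, 93.10, 94.74, 6.90),
    ("rf", "msc+spa", 0, 32, 88.24, 93.75, 90.91, 6.25),
    ("rf", "msc+spa", 1, 18, 78.95, 83.33, 81.08, 16.67),
    ("rf", "msc+spa", 2, 29, 100.00, 89.67, 94.55, 10.33),
    ("rf", "sg+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("rf", "sg+cars", 1, 18, 78.26, 100.00, 87.80, 0.00),
    ("rf", "sg+cars", 2, 29, 100.00, 82.78, 90.58, 17.22),
    ("rf", "snv+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("rf", "snv+cars", 1, 18, 78.26, 100.00, 87.80, 0.00),
    ("rf", "snv+cars", 2, 29, 100.00, 82.76, 90.57, 17.24),
    ("rf", "msc+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("rf", "msc+cars", 1, 18, 85.00, 94.44, 89.47, 5.56),
    ("rf", "msc+cars", 2, 29, 96.30, 89.66, 92.86, 10.34),
    # SVM test-set results
    ("svm", "sg+spa", 0, 32, 100.00, 96.88, 98.42, 3.12),
    ("svm", "sg+spa", 1, 18, 75.00, 100.00, 85.71, 0.00),
    ("svm", "sg+spa", 2, 29, 100.00, 82.76, 90.57, 17.24),
    ("svm", "snv+spa", 0, 32, 100.00, 96.88, 98.42, 3.12),
    ("svm", "snv+spa", 1, 18, 94.74, 100.00, 97.30, 0.00),
    ("svm", "snv+spa", 2, 29, 100.00, 100.00, 100.00, 0.00),
    ("svm", "msc+spa", 0, 32, 100.00, 87.50, 93.33, 12.50),
    ("svm", "msc+spa", 1, 18, 78.26, 100.00, 87.80, 0.00),
    ("svm", "msc+spa", 2, 29, 100.00, 96.66, 98.30, 3.34),
    ("svm", "sg+cars", 0, 32, 100.00, 87.50, 93.33, 12.50),
    ("svm", "sg+cars", 1, 18, 51.42, 100.00, 67.92, 0.00),
    ("svm", "sg+cars", 2, 29, 100.00, 55.17, 71.11, 44.83),
    ("svm", "snv+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("svm", "snv+cars", 1, 18, 85.71, 100.00, 92.31, 0.00),
    ("svm", "snv+cars", 2, 29, 100.00, 89.66, 94.55, 10.34),
    ("svm", "msc+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("svm", "msc+cars", 1, 18, 81.82, 100.00, 90.00, 0.00),
    ("svm", "msc+cars", 2, 29, 100.00, 86.21, 92.59, 13.79),
    # CNN test-set results
    ("cnn", "sg+spa", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "sg+spa", 1, 18, 94.74, 100.00, 97.30, 0.00),
    ("cnn", "sg+spa", 2, 29, 100.00, 96.55, 98.24, 3.45),
    ("cnn", "snv+spa", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "snv+spa", 1, 18, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "snv+spa", 2, 29, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "msc+spa", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "msc+spa", 1, 18, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "msc+spa", 2, 29, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "sg+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "sg+cars", 1, 18, 100.00, 94.44, 97.14, 5.56),
    ("cnn", "sg+cars", 2, 29, 96.67, 100.00, 98.31, 0.00),
    ("cnn", "snv+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "snv+cars", 1, 18, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "snv+cars", 2, 29, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "msc+cars", 0, 32, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "msc+cars", 1, 18, 100.00, 100.00, 100.00, 0.00),
    ("cnn", "msc+cars", 2, 29, 100.00, 100.00, 100.00, 0.00),
    # online-device validation (30 eggs per origin)
    ("online", "rf", 0, 30, 87.10, 90.00, 88.53, 10.00),
    ("online", "rf", 1, 30, 100.00, 80.00, 88.89, 20.00),
    ("online", "rf", 2, 30, 85.71, 100.00, 92.31, 0.00),
    ("online", "svm", 0, 30, 90.63, 96.67, 93.55, 3.33),
    ("online", "svm", 1, 30, 89.66, 86.67, 88.14, 13.33),
    ("online", "svm", 2, 30, 93.10, 90.00, 91.52, 10.00),
    ("online", "cnn", 0, 30, 93.55, 96.67, 95.08, 3.33),
    ("online", "cnn", 1, 30, 96.55, 93.33, 94.91, 6.67),
    ("online", "cnn", 2, 30, 93.33, 93.33, 93.33, 6.67),
]

# overall accuracies reconstructable from (recalls, supports):
# (name, recalls, supports, printed accuracy)
ACCURACY_ROWS = [
    ("rf_best_test", (100.00, 94.44, 96.55), (32, 18, 29), 97.47),
    ("svm_best_test", (96.88, 100.00, 100.00), (32, 18, 29), 98.73),
    ("cnn_best_test", (100.00, 100.00, 100.00), (32, 18, 29), 100.00),
    ("rf_online", (90.00, 80.00, 100.00), (30, 30, 30), 90.00),
    ("svm_online", (96.67, 86.67, 90.00), (30, 30, 30), 91.11),
    ("cnn_online", (96.67, 93.33, 93.33), (30, 30, 30), 94.44),
]
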