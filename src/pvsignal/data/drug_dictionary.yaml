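# Default ingredient dictionary for the dihydropyridine CCB analysis.
#
# `tag: target` marks the four study drugs; `class_background` marks the
# remaining ATC C08CA dihydropyridine ingredients that define the narrowed
# class background. Synonyms are matched case-insensitively after salt/ester
# suffix stripping; add local brand names here as needed.
drugs:
  - name: amlodipine
    tag: target
    synonyms: [NORVASC, KATERZIA, AMVAZ, ISTIN]
  - name: felodipine
    tag: target
    synonyms: [PLENDIL]
  - name: nicardipine
    tag: target
    synonyms: [CARDENE]
  - name: nifedipine
    tag: target
    synonyms: [ADALAT, PROCARDIA, AFEDITAB, NIFEDIAC]
  - name: nimodipine
    tag: class_background
    synonyms: [NIMOTOP, NYMALIZE]
  - name: nisoldipine
    tag: class_background
    synonyms: [SULAR]
  - name: nitrendipine
    tag: class_background
    synonyms: [BAYPRESS]
  - name: isradipine
    tag: class_background
    synonyms: [DYNACIRC]
  - name: lacidipine
    tag: class_background
    synonyms: [MOTENS]
  - name: lercanidipine
    tag: class_background
    synonyms: [ZANIDIP]
  - name: manidipine
    tag: class_background
    synonyms: [MANYPER]
  - name: barnidipine
    tag: class_background
    synonyms: [VASEXTEN]
  - name: cilnidipine
    tag: class_background
    synonyms: [ATELEC]
  - name: benidipine
    tag: class_background
    synonyms: [CONIEL]
  - name: clevidipine
    tag: class_background
    synonyms: [CLEVIPREX]
  - name: nilvadipine
    tag: class_background
    synonyms: [NIVADIL]
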