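# Default keyword ruleset for pulling patient-experience candidate posts.
#
# Only the care-condition list is the study's published list; the other six
# class lists are small PLACEHOLDER sets (the full curated lists are not
# public) and are expected to be replaced for any real deployment.
#
# classes: class name -> list of keywords, matched case-insensitively on
#   word boundaries.  prefix_classes: classes whose keywords also match as
#   word prefixes ("recover" -> "recovery"); default none.
# rules: list of conjunctions over class names; a post enters the corpus if
#   at least one rule has every named class matched.

classes:
  care condition:
    - monitor
    - heal
    - recover
    - care
    - cure
    - dying
    - dead
    - sicker
    - sick
    - ill
    - illness
    - condition
  medical facilities and staff:   # placeholder list
    - hospital
    - clinic
    - doctor
    - nurse
    - surgeon
    - physician
    - dentist
    - emergency room
    - er
  medical procedures:             # placeholder list
    - surgery
    - operation
    - procedure
    - checkup
    - scan
    - x-ray
    - biopsy
    - transplant
  hospital visits and stays:      # placeholder list
    - admitted
    - discharged
    - ward
    - appointment
    - waiting room
    - visit
    - stay
  medications:                    # placeholder list
    - medication
    - medicine
    - prescription
    - pills
    - antibiotics
    - dose
  hospital bills and insurance:   # placeholder list
    - insurance
    - copay
    - deductible
    - bill
    - billing
    - coverage
  pain:                           # placeholder list
    - pain
    - ache
    - hurting
    - sore

prefix_classes: []

rules:
  - [care condition]
  - [medical facilities and staff]
  - [medical procedures]
  - [hospital visits and stays]
  - [medications]
  - [hospital bills and insurance]
  - [pain]
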