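# Words counted as a reference to hospital staff (binary classifier feature).
doctor
doctors
dr
nurse
nurses
surgeon
surgeons
physician
physicians
medic
medics
paramedic
paramedics
therapist
therapists
dentist
dentists
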