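pt,scope
Alopecia,narrow
Alopecia areata,narrow
Alopecia totalis,narrow
Alopecia universalis,narrow
Androgenetic alopecia,narrow
Diffuse alopecia,narrow
Hypotrichosis,narrow
Alopecia scarring,narrow
Injection site alopecia,narrow
Application site alopecia,narrow
Non-scarring alopecia,narrow
Loose anagen syndrome,narrow
Seborrhoeic alopecia,narrow
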