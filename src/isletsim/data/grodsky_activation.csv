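glycemia_mg_dl,percent_activation
50,2
100,18.75
150,43.75
200,56.25
300,75
500,100
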