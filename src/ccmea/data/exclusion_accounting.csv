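item,count
screened,551
suspected_ibd,6
inadequate_bowel_preparation,15
failed_cecal_intubation,7
no_biopsies,8
cancerous_obstruction,5
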