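category,grade_pair,n
first_higher,5/4,2
first_higher,6/4,1
first_higher,6/5,2
first_higher,7/5,2
first_higher,7/6,4
equal,4/4,1
equal,5/5,1
equal,6/6,0
equal,7/7,1
second_higher,4/5,0
second_higher,5/6,1
second_higher,6/7,1
sum,first_higher,11
sum,equal,3
sum,second_higher,1
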