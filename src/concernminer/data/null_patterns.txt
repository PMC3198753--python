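# Null-pattern bank: responses that convey no health information.
# One pattern per line; matched exactly after normalization
# (lowercase, punctuation/digits stripped, whitespace collapsed).
# Synthetic fixture bank (~60 entries); the original production bank
# of 670 patterns is not redistributable.
No
no
NO
No.
N/A
n/a
NA
na
N.A.
none
None
NONE
nothing
Nothing
nothing to add
Nothing to add.
nothing to report
nothing at this time
nothing else
nothing further
nothing comes to mind
I have nothing to say
i have nothing to say
nothing to say
no comment
no comments
no concerns
no concerns at this time
no other concerns
no additional concerns
no health concerns
no issues
no problems
no thank you
no thanks
not at this time
not really
not applicable
not now
nope
nah
negative
all good
all is well
i'm fine
im fine
I am fine
fine
doing fine
everything is fine
good
i'm good
all covered
covered everything
see above
same as above
no nothing
no sir
no ma'am
zero
-
.
?
x
xx
xxx
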